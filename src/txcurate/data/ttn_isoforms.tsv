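transcript_id	protein_length_aa	shared_with_other_catalogs
ENST00000412264.1	48	no
ENST00000448510.2	172	no
ENST00000436599.1	213	no
ENST00000425332.2	240	no
ENST00000426232.5	255	no
ENST00000634225.1	353	no
ENST00000446966.1	372	no
ENST00000414766.5	962	no
ENST00000360870.10	5604	yes
ENST00000460472.6	26926	yes
ENST00000359218.10	27051	yes
ENST00000342175.11	27118	yes
ENST00000342992.11	33423	yes
ENST00000591111.5	34350	yes
ENST00000589042.5	35991	yes
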