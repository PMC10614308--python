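# txcurate

A curation toolkit for transcript catalogs built from large-scale RNA-seq
assembly. Expression-driven annotation pipelines assemble millions of
transcripts, the overwhelming majority of which are noise: isoforms
without a valid open reading frame, splice junctions seen in a handful of
samples, severely truncated proteins, well-structured fragments,
duplicates, and read-through artifacts. `txcurate` implements the curation
machinery that separates the durable protein-coding catalog from that
noise, and the comparison tools used to audit the result against other
annotation databases.

## What it does

* **ORF assignment** (`orf_assign`): copies CDS chains from a reference
  annotation onto assembled transcripts when the copy is exact (every
  reference CDS segment inside the target's exons, every CDS-internal
  intron matched), and otherwise falls back to the longest forward-frame
  ATG..stop ORF of at least 25 aa.
* **The filter cascade** (`filter_cascade`): an ordered, auditable set of
  rules over candidate coding transcripts

  `orf_validity → intron_support → truncation → structure_gate →
  substring → containment → fragment → dedup → readthrough`

  with the published defaults: proteins shorter than 1/5 of the longest
  isoform at their locus are dropped (unless whitelisted with independent
  evidence of function); candidates are kept only if their predicted
  structure is confident (mean pLDDT ≥ 70); proteins that are substrings
  of the established "beta" set are removed; proteins containing a beta
  protein survive only as the top-scoring isoform of their locus;
  fragments (< 70 aa, or < 2/3 of the locus maximum) are removed;
  identical proteins are deduplicated preferring reference-matching intron
  chains and then sample support; and transcripts whose exons span two
  same-strand gene loci are removed as read-through artifacts. Every
  stage logs one keep/drop decision per transcript.
* **Catalog comparison** (`catalog_compare`): two transcripts match when
  *all of their introns match precisely* (identical intron chains).  On
  that equivalence: one-way catalog matching, three-way Venn partitions of
  distinct chains, per-gene protein length-ratio censuses, biotype
  summaries, alternative-splicing event classification against a
  canonical (MANE-style) isoform, and screening for novel isoforms with
  cumulative TPM > 1000 that carry > 50 % of their locus's expression.
* **Splice-site conservation** (`conservation`): for every intron, counts
  how many species in a MAF whole-genome alignment preserve the GT/AG
  consensus dinucleotides at both boundaries, read in transcript
  orientation, and histograms the counts per biotype.
* **Synthetic fixtures** (`fixtures`): deterministic genomes, catalogs
  with planted defect classes, score/support tables and alignments with
  planted conservation patterns, so the whole pipeline is testable
  offline from standard file formats.

## Worked example: the Titin truncation rule

Titin (TTN) encodes the longest human protein, 35,991 aa. One widely used
annotation database lists 15 protein-coding TTN isoforms ranging from 48
to 35,991 aa, eight of them shorter than 1000 aa and almost certainly
non-functional. The packaged isoform table reproduces the truncation
filter's behaviour on this locus:

```python
>>> from txcurate.fixtures import ttn_isoform_lengths, TTN_SHORT_FUNCTIONAL_ISOFORM
>>> from txcurate.filter_cascade import truncation_keep
>>> lengths = ttn_isoform_lengths()
>>> len(lengths), max(lengths.values()), min(lengths.values())
(15, 35991, 48)
>>> kept = truncation_keep(lengths)          # threshold = 35991/5 = 7198.2
>>> sorted(lengths[t] for t in kept)
[26926, 27051, 27118, 33423, 34350, 35991]
>>> len(truncation_keep(lengths, {TTN_SHORT_FUNCTIONAL_ISOFORM}))
7
```

Six isoforms clear one-fifth of the maximum length; whitelisting the
5604 aa isoform — which has experimental evidence of transcription,
translation and function — retains a seventh. This is exactly how the
curated catalogs treat this locus: no TTN isoform under 1000 aa survives,
while the evidence-backed short form does.

## Command line

Each task is a subcommand of `txcurate` (`orf`, `filter`, `compare`,
`census`, `events`, `screen`, `conserve`, `simulate`, `summarize`):

```bash
txcurate simulate --seed 7 --out-dir demo/
txcurate filter --catalog demo/candidates.gtf --beta demo/beta.gtf \
    --scores demo/plddt.tsv --support demo/support.tsv \
    --reference demo/reference.gtf --genome demo/genome.fa \
    --out demo/final.gtf --report demo/stages.tsv --decisions demo/decisions.tsv
```

The stage report for the default simulated bundle (200 candidates, seven
planted defect classes) reads:

```
orf_validity    200 193
intron_support  193 187
truncation      187 182
structure_gate  182 172
substring       172 166
containment     166 166
fragment        166 166
dedup           166 162
readthrough     162 159
```

i.e. each planted defect class is removed at exactly its stage and the
159 clean transcripts survive.

## Layout

```
src/txcurate/
  annot_io.py        data model, GTF/GFF3 + FASTA I/O, translation
  orf_assign.py      CDS projection and longest-ORF fallback
  filter_cascade.py  the nine curation stages and their composition
  catalog_compare.py intron-chain matching, Venn, censuses, AS events
  conservation.py    MAF parsing and GT/AG boundary conservation
  fixtures.py        deterministic synthetic data + packaged tables
  cli.py             the `txcurate` command
docs/methods.md      the model, parameters, and design rationale
```
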