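# Methods

## The problem and the model

Assembling transcripts from thousands of RNA-seq samples yields catalogs
in which genuine isoforms are buried in transcriptional noise. `txcurate`
models curation as a deterministic, ordered cascade of per-transcript
rules over three inputs: the candidate transcripts themselves (exon
chains, optional CDS chains, expression support), an established
reference annotation (a source of trusted intron coordinates and CDS
chains), and a per-protein structure-confidence table (mean pLDDT, the
0–100 per-residue confidence of an AlphaFold2-class predictor averaged
over the protein; predictions with mean pLDDT ≥ 70 are conventionally
considered confident). Two transcripts are treated as the same isoform
exactly when their intron chains are identical; this one equivalence
underlies matching, deduplication, Venn partitions and the novel-isoform
screen.

## Coordinates and conventions

All interface coordinates are 1-based and inclusive on both ends (the GTF
convention); intron `(donor, acceptor)` pairs are the first and last
intron base in forward genomic coordinates. Stored CDS chains are
normalized to include the stop codon: `stop_codon` features encountered
on input are merged into the CDS chain, and translation always strips the
trailing stop from the protein. This one internal convention absorbs the
GTF/GFF3 stop-codon dialect difference, mirroring the usual
stop-adjustment normalization applied before comparing CDS annotations
across databases. Translation uses the standard genetic code; an internal
stop codon or a CDS length not divisible by 3 marks the ORF invalid — a
flag consumed by the cascade rather than a parse error, because noisy
catalogs legitimately contain such records.

## ORF assignment

A coding transcript without a CDS first tries reference projection:
copying the CDS chain of a same-chromosome, same-strand reference
transcript. Projection succeeds only when it is exact — every reference
CDS segment lies within a single target exon and every reference intron
inside the CDS span occurs identically in the target chain — which
guarantees the projected protein equals the reference protein. Among
projectable references the one sharing the most coding bases with the
target wins (ties: lexicographically smallest reference id). Failing
projection, the longest ATG-initiated, stop-terminated ORF across the
three forward frames of the spliced sequence is used, with a 25 aa floor
(the length of the shortest protein in curated human annotation, RPL41);
length ties resolve to the 5′-most start. Non-ATG initiation and
selenoprotein recoding are out of scope.

## The cascade, stage by stage

Defaults in parentheses; all are configurable (`CascadeConfig`).

1. **orf_validity** — coding transcripts must carry a valid ATG..stop ORF
   (mod-3 length, no internal stop, start and stop codons present).
   Non-coding biotypes are exempt.
2. **intron_support** — every intron must either match a reference intron
   exactly or be canonical (GT/AG) *and* carried by a transcript
   assembled in at least `min_samples` (3) samples. This is a transparent
   surrogate for learned intron-confidence classifiers; 3 samples is this
   package's choice of a minimal reproducibility floor, since the rule's
   original form is a trained model rather than a threshold.
3. **truncation** — per gene, proteins shorter than 1/5 of the longest
   isoform are dropped unless whitelisted. The whitelist is an explicit
   curation input (ids or tags), because "independent evidence of
   function" — clinically significant short isoforms, experimentally
   validated short forms — is not computable from the catalog itself.
4. **structure_gate** — keep candidates with mean pLDDT ≥ 70. The
   boundary is inclusive. Candidates without a score are dropped: an
   unscorable protein cannot pass a confidence gate. (In practice
   structure predictors cap input length; the gate treats "too long to
   score" and "not scored" identically.)
5. **substring** — candidate proteins that are contiguous substrings of
   (or equal to) any established beta protein are redundant and dropped.
   Matching is genome-wide by default (`substring_per_locus` restricts
   it), following the unqualified form of the rule.
6. **containment** — a candidate strictly containing a beta protein of
   its locus survives only if its score is the locus maximum over all
   scored isoforms (candidate and beta); a tie keeps the candidate.
7. **fragment** — drop proteins < 70 aa, or < 2/3 of the longest protein
   at the locus (equality keeps; boundaries follow the literal wording of
   the rule: "shorter than" and "less than" are strict). When the cascade
   runs with a beta set, beta proteins at the locus contribute to the
   maximum, so fragments are judged against established full-length
   isoforms, not only against other candidates.
8. **dedup** — one survivor per (locus, identical protein): first a
   multi-exon transcript whose chain matches a reference transcript, then
   the largest sample count, then the lexicographically smallest id. The
   reference-chain priority is restricted to multi-exon transcripts
   because an empty intron chain would vacuously "match" any single-exon
   reference; single-exon groups fall through to the support rules. The
   final lexicographic tie-break exists purely for determinism.
9. **readthrough** — drop candidates whose exons overlap exons of two or
   more distinct same-strand gene loci. Overlap is exonic and
   strand-matched so that genes nested in another gene's introns, and
   antisense overlaps, never trigger removal.

Locus identity is the gene id of the catalog under construction; a
candidate without an established gene id inherits the beta gene it
overlaps most in exonic bases. The cascade is monotone (each stage's
output feeds the next), fully logged (one decision per transcript per
stage reached), and deterministic: identical inputs produce byte-identical
decision logs.

## Catalog comparison

Matching is by identical intron chain (chromosome, strand, all intron
coordinates). The criterion is undefined for single-exon transcripts; the
package matches those on identical CDS genomic span (exon span for
non-coding), the strictest reading consistent with the intron-precision
spirit, and Venn counting can exclude them entirely
(`multi_exon_only`). Venn units are distinct chains, so duplicate chains
within one catalog count once. Alternative-splicing events against a
canonical isoform: an intron fully spanning a complete canonical exon is
exon skipping (coordinates: the spanning intron); an exon fully
containing a canonical intron with at least 1 nt of both flanking
canonical exons is intron retention (coordinates: the retained intron);
CDS 5′/3′ genomic boundary differences, strand-aware, are alternative
start/stop. The novel-isoform screen requires, jointly: no exact-chain
match in any reference, a protein not string-identical to any reference
protein, cumulative TPM strictly above 1000, and strictly more than 50 %
of the summed TPM of the gene's transcripts.

## Conservation counting

For each intron, the four boundary bases (first two and last two) are
mapped through the alignment columns of a MAF file; a species preserves
the intron when its donor 2-mer reads GT and its acceptor 2-mer reads AG
in transcript orientation (minus-strand introns are reverse-complemented
and swapped). Conservation requires *both* boundaries. A species gapped
or absent at any of the four columns preserves nothing — a gap preserves
no dinucleotide. The reference species is counted like any other, so an
intron with canonical reference boundaries scores at least 1, and a
non-canonical (e.g. GC–AG) reference intron scores 0 under the literal
GT/AG rule; a consensus allow-list parameter admits canonical variants if
wanted. Only the four boundary columns are mapped, never the intron body,
so introns spanning multiple alignment blocks are handled naturally.
Histograms are over distinct introns (deduplicated across transcripts),
covered introns only; bin counts therefore sum to the number of covered
introns.

## Synthetic data: what it emulates, and what it does not

The generators produce the study conditions at desk scale: 40 genes with
2–8 isoforms each (200 transcripts, averaging five isoforms per gene, the
density typical of curated human protein-coding annotation), with seven
planted defect classes — 7 invalid ORFs, 6 unsupported novel introns,
5 truncated isoforms, 10 low-pLDDT candidates, 6 substring proteins,
4 duplicate proteins and 3 read-through artifacts — each constructed so
that exactly one cascade stage removes it. Proteins are 100 aa
(fragments and truncations scaled accordingly), structure scores are
drawn in 71–95 for confident and 40–62 for low-confidence classes, clean
transcripts carry 20-sample support, unsupported introns 1. The
conservation generator realizes an explicit per-intron plan of preserving
species over a 30-species panel (a primate-heavy clade plus three outgroup
mammals) by substituting or gapping boundary bases in non-preserving
species.

Each transcript occupies its own genomic block with a back-translated
CDS (fixed codon per amino acid) stamped into random background sequence.
This gives exact control — translation, splice boundaries and protein
identity are correct by construction — but means isoforms of one gene do
not share genomic sequence, alignments contain no rearrangements, and
expression values are summary totals rather than read-level quantities.
Passing tests therefore demonstrate the correctness of the curation
*bookkeeping* (rule logic, ordering, determinism, format round-trips) on
realistic structures, not performance on real read data, and the
genome-scale catalog counts published for real builds are out of reach by
design.

## Numerical and degenerate-input choices

Threshold boundary semantics are fixed as: structure gate inclusive
(≥ 70); truncation strict (< L/5 drops); fragment strict (< 70 aa,
< 2/3·L drop, equality keeps). Single-isoform loci are never touched by
the truncation rule. Empty candidate sets flow through the cascade and
produce all-zero reports. Duplicate species rows in one MAF block: the
first row wins, with a warning. Collisions where several subject
transcripts share a chain resolve to the lexicographically smallest id.
Support values missing from the expression table default to zero — no
support — which is the conservative direction for every filter that
consumes them.

## Problem sizes

The shipped tests and the acceptance script run on the 200-transcript
bundle, catalogs of ≤ 500 transcripts for brute-force cross-checks, and
alignments of 3–30 species over ~10–20 kb of sequence; the whole suite
completes in a few seconds. These sizes were chosen so that every check
against an exhaustive oracle (all-pairs chain comparison, per-predicate
re-derivation of the cascade) is feasible exactly, with no sampling.

## Known limitations

* The intron-support rule is a deliberately simple stand-in for trained
  intron classifiers; it cannot capture context beyond canonicity and
  sample counts.
* Projection is exact-only; near-miss CDS projections (frame-preserving
  small indels) fall back to the longest-ORF search.
* The substring and containment rules compare exact amino-acid strings;
  no similarity tolerance.
* Conservation counting asks only about the four boundary bases; it says
  nothing about intron-body or exon conservation.
* Single-exon transcript matching has no community-agreed definition; the
  CDS-span rule here is one defensible choice and is configurable only
  between strict variants.
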