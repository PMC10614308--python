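"""The protein-coding filter cascade: ordered, auditable curation rules.

Expression-driven transcript assembly produces large numbers of aberrant
isoforms — invalid ORFs, unsupported splice junctions, severely truncated
proteins, fragments that score well structurally, duplicates and
read-through artifacts.  This module implements the curation rules that
remove them as an ordered cascade.  Every stage returns a filtered catalog
plus one :class:`FilterDecision` per transcript it evaluated, and
:func:`run_full_cascade` / :func:`run_candidate_cascade` compose the stages
and emit a monotone :class:`StageReport`.

Stage order (full cascade)::

    orf_validity -> intron_support -> truncation ->
    structure_gate -> substring -> containment -> fragment ->
    dedup -> readthrough

The last six stages form the *candidate* cascade, which screens
structure-scored candidate transcripts against an established protein set
("beta" proteins) before merging the survivors into it.  The gate keeps a
candidate only when its predicted structure is confident (mean pLDDT at or
above 70 by default); candidates without a score are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annot_io import (
    Catalog,
    CatalogError,
    Genome,
    ProteinRecord,
    Transcript,
    as_genome,
    intron_chain_of,
    orf_flaws,
    try_translate,
)

__all__ = [
    "StructureScoreTable",
    "FilterDecision",
    "StageReport",
    "CascadeConfig",
    "CascadeResult",
    "STAGES",
    "CANDIDATE_STAGES",
    "translate_catalog",
    "orf_validity_filter",
    "intron_support_filter",
    "truncation_filter",
    "truncation_keep",
    "structure_gate",
    "substring_filter",
    "containment_resolution",
    "fragment_filter",
    "dedup_identical",
    "readthrough_filter",
    "assign_loci",
    "run_candidate_cascade",
    "run_full_cascade",
]

STAGES = (
    "orf_validity",
    "intron_support",
    "truncation",
    "structure_gate",
    "substring",
    "containment",
    "fragment",
    "dedup",
    "readthrough",
)

CANDIDATE_STAGES = STAGES[3:]


class StructureScoreTable:
    """Map protein_id -> mean pLDDT (structure-prediction confidence, 0-100)."""

    def __init__(self, scores: Mapping[str, float] | None = None):
        self._scores: dict[str, float] = {}
        if scores:
            for pid, value in scores.items():
                self[pid] = value

    def __setitem__(self, protein_id: str, value: float) -> None:
        value = float(value)
        if not 0.0 <= value <= 100.0:
            raise CatalogError(f"pLDDT {value} for {protein_id} outside [0, 100]")
        self._scores[protein_id] = value

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._scores

    def __len__(self) -> int:
        return len(self._scores)

    def get(self, protein_id: str) -> float | None:
        return self._scores.get(protein_id)

    def items(self):
        return self._scores.items()

    @classmethod
    def from_tsv(cls, path: str | Path) -> "StructureScoreTable":
        """Read a 2-column TSV (protein_id, mean_plddt); header optional."""
        table = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise CatalogError(f"{path}:{lineno}: expected 2 columns")
                if lineno == 1 and parts[0] in ("protein_id", "id"):
                    continue
                table[parts[0]] = float(parts[1])
        return table


@dataclass(frozen=True)
class FilterDecision:
    transcript_id: str
    stage: str
    action: str  # "keep" | "drop"
    reason: str


@dataclass
class StageReport:
    """Ordered (stage, transcripts_in, transcripts_out) rows."""

    rows: list[tuple[str, int, int]] = field(default_factory=list)

    def append(self, stage: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise CatalogError(f"stage {stage}: out {n_out} > in {n_in}")
        if self.rows and self.rows[-1][2] != n_in:
            raise CatalogError(
                f"stage {stage}: in {n_in} != previous out {self.rows[-1][2]}"
            )
        self.rows.append((stage, n_in, n_out))

    def to_tsv(self) -> str:
        lines = ["stage\ttranscripts_in\ttranscripts_out"]
        lines += [f"{s}\t{i}\t{o}" for s, i, o in self.rows]
        return "\n".join(lines) + "\n"


@dataclass
class CascadeConfig:
    """All tunable thresholds, with the published curation defaults."""

    plddt_threshold: float = 70.0    # structure gate, inclusive ("70 or above")
    min_protein_aa: int = 70         # fragment rule (a): strict <70 drops
    fragment_fraction: float = 2 / 3  # fragment rule (b): strict < drops
    truncation_fraction: float = 1 / 5  # truncation rule: strict < drops
    min_samples: int = 3             # novel-intron sample support floor
    min_aa_orf: int = 25             # fallback ORF search floor
    min_tpm: float = 1000.0          # novel-isoform screen
    novel_fraction: float = 0.5      # novel-isoform expression dominance
    substring_per_locus: bool = False

    def __post_init__(self) -> None:
        for name in ("fragment_fraction", "truncation_fraction",
                     "novel_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise CatalogError(f"{name}={v} outside (0, 1]")
        for name in ("plddt_threshold", "min_protein_aa", "min_samples",
                     "min_aa_orf", "min_tpm"):
            if getattr(self, name) < 0:
                raise CatalogError(f"{name} must be >= 0")


def translate_catalog(catalog: Catalog, genome
                      ) -> tuple[dict[str, ProteinRecord], dict[str, str]]:
    """Translate every coding transcript; return (proteins, flaw reasons)."""
    g = as_genome(genome)
    proteins: dict[str, ProteinRecord] = {}
    flaws: dict[str, str] = {}
    for t in catalog.transcripts():
        if not t.is_coding:
            continue
        protein, reason = try_translate(t, g)
        if protein is not None:
            proteins[t.transcript_id] = protein
        else:
            flaws[t.transcript_id] = reason
    return proteins, flaws


def _split(catalog: Catalog, decisions: list[FilterDecision]) -> Catalog:
    dropped = {d.transcript_id for d in decisions if d.action == "drop"}
    return catalog.subset(t for t in catalog.transcript_ids()
                          if t not in dropped)


# ---------------------------------------------------------------------------
# Beta-set stages


def orf_validity_filter(catalog: Catalog, genome
                        ) -> tuple[Catalog, list[FilterDecision]]:
    """Drop coding transcripts without a valid ATG..stop ORF.

    Invalid means: no CDS, internal stop codon, CDS length not a multiple
    of 3, or missing start/stop codon.  Non-coding biotypes are exempt.
    """
    g = as_genome(genome)
    decisions: list[FilterDecision] = []
    for t in catalog.transcripts():
        if not t.is_coding:
            decisions.append(FilterDecision(t.transcript_id, "orf_validity",
                                            "keep", "noncoding_exempt"))
            continue
        flaws = orf_flaws(t, g)
        if flaws:
            decisions.append(FilterDecision(t.transcript_id, "orf_validity",
                                            "drop",
                                            "invalid_orf:" + ",".join(flaws)))
        else:
            decisions.append(FilterDecision(t.transcript_id, "orf_validity",
                                            "keep", "valid_orf"))
    return _split(catalog, decisions), decisions


def intron_support_filter(catalog: Catalog, ref: Catalog, min_samples: int,
                          genome=None
                          ) -> tuple[Catalog, list[FilterDecision]]:
    """Keep transcripts whose every intron is reference-matched or supported.

    An intron passes if it matches an intron of ``ref`` exactly, or if it
    has canonical GT/AG boundaries in the genome *and* the transcript was
    assembled in at least ``min_samples`` samples.  This is a transparent
    rule-based surrogate for learned intron-confidence classifiers.
    """
    ref_introns = ref.intron_set()
    g = as_genome(genome) if genome is not None else None
    decisions: list[FilterDecision] = []
    for t in catalog.transcripts():
        chain = intron_chain_of(t)
        verdict: tuple[str, str] = ("keep", "introns_supported")
        for donor, acceptor in chain.introns:
            if (chain.chrom, chain.strand, donor, acceptor) in ref_introns:
                continue
            if g is None:
                raise CatalogError(
                    f"{t.transcript_id}: genome required to evaluate "
                    f"non-reference intron {chain.chrom}:{donor}-{acceptor}"
                )
            if not _canonical_boundaries(g, chain, donor, acceptor):
                verdict = ("drop", "noncanonical_novel_intron")
                break
            if t.n_samples < min_samples:
                verdict = ("drop", "unsupported_novel_intron")
                break
        decisions.append(FilterDecision(t.transcript_id, "intron_support",
                                        *verdict))
    return _split(catalog, decisions), decisions


_RC = str.maketrans("ACGT", "TGCA")


def _canonical_boundaries(g: Genome, chain, donor: int, acceptor: int) -> bool:
    five = g.fetch(chain.chrom, donor, donor + 1)
    three = g.fetch(chain.chrom, acceptor - 1, acceptor)
    if chain.strand == "-":
        five, three = three.translate(_RC)[::-1], five.translate(_RC)[::-1]
    return five == "GT" and three == "AG"


def truncation_keep(lengths: Mapping[str, int],
                    whitelist: frozenset[str] | set[str] = frozenset(),
                    fraction: float = 1 / 5) -> set[str]:
    """Apply the truncation rule to one locus's protein lengths.

    With ``L`` the maximum protein length at the locus, any protein
    strictly shorter than ``fraction * L`` is considered non-functional
    unless its id is whitelisted.  Returns the surviving ids.
    """
    if not lengths:
        return set()
    threshold = fraction * max(lengths.values())
    return {tid for tid, aa in lengths.items()
            if aa >= threshold or tid in whitelist}


def truncation_filter(catalog: Catalog,
                      proteins: Mapping[str, ProteinRecord],
                      whitelist: Iterable[str] = (),
                      fraction: float = 1 / 5
                      ) -> tuple[Catalog, list[FilterDecision]]:
    """Drop severely truncated isoforms per gene locus.

    Whitelisting (by transcript id or tag) exempts isoforms with
    independent evidence of function.  Loci with a single isoform are
    untouched.  Transcripts without a translated protein are passed
    through (upstream stages own ORF validity).
    """
    wl = frozenset(whitelist)
    decisions: list[FilterDecision] = []
    for gene_id, transcripts in catalog.genes.items():
        lengths = {t.transcript_id: proteins[t.transcript_id].length_aa
                   for t in transcripts if t.transcript_id in proteins}
        if len(lengths) <= 1:
            for t in transcripts:
                decisions.append(FilterDecision(
                    t.transcript_id, "truncation", "keep", "single_isoform"
                    if t.transcript_id in lengths else "no_protein"))
            continue
        keep = truncation_keep(lengths, wl, fraction)
        threshold = fraction * max(lengths.values())
        for t in transcripts:
            tid = t.transcript_id
            if tid not in lengths:
                decisions.append(FilterDecision(tid, "truncation", "keep",
                                                "no_protein"))
            elif lengths[tid] >= threshold:
                decisions.append(FilterDecision(tid, "truncation", "keep",
                                                "above_threshold"))
            elif tid in keep or t.tags & wl:
                decisions.append(FilterDecision(tid, "truncation", "keep",
                                                "whitelisted"))
            else:
                decisions.append(FilterDecision(
                    tid, "truncation", "drop",
                    f"truncated:{lengths[tid]}aa<{threshold:.1f}"))
    return _split(catalog, decisions), decisions


# ---------------------------------------------------------------------------
# Candidate stages


def structure_gate(candidates: Catalog, scores: StructureScoreTable,
                   threshold: float = 70.0
                   ) -> tuple[Catalog, list[FilterDecision]]:
    """Keep candidates whose mean pLDDT is at or above ``threshold``.

    Candidates without a score are dropped (reason ``unscored``); a
    structure prediction too long or missing means the confidence gate
    cannot be applied.
    """
    decisions: list[FilterDecision] = []
    for t in candidates.transcripts():
        score = scores.get(t.transcript_id)
        if score is None:
            verdict = ("drop", "unscored")
        elif score >= threshold:
            verdict = ("keep", f"plddt:{score:g}")
        else:
            verdict = ("drop", f"low_plddt:{score:g}<{threshold:g}")
        decisions.append(FilterDecision(t.transcript_id, "structure_gate",
                                        *verdict))
    return _split(candidates, decisions), decisions


def substring_filter(candidates: Catalog,
                     proteins: Mapping[str, ProteinRecord],
                     beta_proteins: Iterable[ProteinRecord],
                     per_locus: bool = False,
                     beta_locus: Mapping[str, str] | None = None
                     ) -> tuple[Catalog, list[FilterDecision]]:
    """Drop candidates whose protein is a substring of any beta protein.

    Equality counts as a substring.  By default matching is genome-wide;
    with ``per_locus`` only beta proteins of the candidate's own locus
    (via ``beta_locus``: protein_id -> gene_id) are compared.
    """
    beta = list(beta_proteins)
    decisions: list[FilterDecision] = []
    for t in candidates.transcripts():
        protein = proteins.get(t.transcript_id)
        if protein is None:
            decisions.append(FilterDecision(t.transcript_id, "substring",
                                            "keep", "no_protein"))
            continue
        pool = beta
        if per_locus:
            if beta_locus is None:
                raise CatalogError("per_locus substring needs beta_locus map")
            pool = [b for b in beta
                    if beta_locus.get(b.protein_id) == t.gene_id]
        hit = next((b.protein_id for b in pool
                    if protein.sequence in b.sequence), None)
        if hit is not None:
            decisions.append(FilterDecision(t.transcript_id, "substring",
                                            "drop", f"substring_of:{hit}"))
        else:
            decisions.append(FilterDecision(t.transcript_id, "substring",
                                            "keep", "not_substring"))
    return _split(candidates, decisions), decisions


def containment_resolution(candidates: Catalog,
                           proteins: Mapping[str, ProteinRecord],
                           beta: Catalog,
                           beta_proteins: Mapping[str, ProteinRecord],
                           scores: StructureScoreTable
                           ) -> tuple[Catalog, list[FilterDecision]]:
    """Resolve candidates whose protein strictly contains a beta protein.

    Such a candidate survives only if its structure score is the maximum
    over all scored isoforms (candidate and beta) at its gene locus; a tie
    with the locus maximum keeps the candidate.
    """
    beta_by_gene: dict[str, list[str]] = {}
    for t in beta.transcripts():
        if t.transcript_id in beta_proteins:
            beta_by_gene.setdefault(t.gene_id, []).append(t.transcript_id)

    decisions: list[FilterDecision] = []
    for gene_id, transcripts in candidates.genes.items():
        locus_scores = []
        for t in transcripts:
            s = scores.get(t.transcript_id)
            if s is not None and t.transcript_id in proteins:
                locus_scores.append(s)
        for bid in beta_by_gene.get(gene_id, ()):
            s = scores.get(bid)
            if s is not None:
                locus_scores.append(s)
        locus_max = max(locus_scores) if locus_scores else None
        for t in transcripts:
            tid = t.transcript_id
            protein = proteins.get(tid)
            contained = None
            if protein is not None:
                for bid in beta_by_gene.get(gene_id, ()):
                    bseq = beta_proteins[bid].sequence
                    if bseq != protein.sequence and bseq in protein.sequence:
                        contained = bid
                        break
            if contained is None:
                decisions.append(FilterDecision(tid, "containment", "keep",
                                                "no_containment"))
                continue
            score = scores.get(tid)
            if score is not None and locus_max is not None \
                    and score >= locus_max:
                decisions.append(FilterDecision(
                    tid, "containment", "keep",
                    f"contains:{contained};locus_best:{score:g}"))
            else:
                decisions.append(FilterDecision(
                    tid, "containment", "drop",
                    f"contains:{contained};not_locus_best"))
    return _split(candidates, decisions), decisions


def fragment_filter(candidates: Catalog,
                    proteins: Mapping[str, ProteinRecord],
                    min_aa: int = 70,
                    fraction: float = 2 / 3,
                    beta: Catalog | None = None,
                    beta_proteins: Mapping[str, ProteinRecord] | None = None
                    ) -> tuple[Catalog, list[FilterDecision]]:
    """Drop probable fragments: short proteins or short relative to locus.

    Rule (a): strictly shorter than ``min_aa`` amino acids.  Rule (b):
    strictly shorter than ``fraction`` of the longest protein at the same
    locus (equality keeps).  When a beta catalog is supplied its proteins
    contribute to each locus's maximum, so candidate fragments are judged
    against the established full-length isoforms too.
    """
    beta_len_by_gene: dict[str, int] = {}
    if beta is not None and beta_proteins is not None:
        for t in beta.transcripts():
            p = beta_proteins.get(t.transcript_id)
            if p is not None:
                prev = beta_len_by_gene.get(t.gene_id, 0)
                beta_len_by_gene[t.gene_id] = max(prev, p.length_aa)

    decisions: list[FilterDecision] = []
    for gene_id, transcripts in candidates.genes.items():
        lengths = [proteins[t.transcript_id].length_aa for t in transcripts
                   if t.transcript_id in proteins]
        locus_max = max(lengths + [beta_len_by_gene.get(gene_id, 0)],
                        default=0)
        for t in transcripts:
            tid = t.transcript_id
            protein = proteins.get(tid)
            if protein is None:
                decisions.append(FilterDecision(tid, "fragment", "keep",
                                                "no_protein"))
                continue
            if protein.length_aa < min_aa:
                decisions.append(FilterDecision(
                    tid, "fragment", "drop",
                    f"short:{protein.length_aa}aa<{min_aa}"))
            elif protein.length_aa < fraction * locus_max:
                decisions.append(FilterDecision(
                    tid, "fragment", "drop",
                    f"fragment:{protein.length_aa}aa<"
                    f"{fraction * locus_max:.1f}"))
            else:
                decisions.append(FilterDecision(tid, "fragment", "keep",
                                                "full_length"))
    return _split(candidates, decisions), decisions


def dedup_identical(candidates: Catalog,
                    proteins: Mapping[str, ProteinRecord],
                    ref_catalogs: Sequence[Catalog] = ()
                    ) -> tuple[Catalog, list[FilterDecision]]:
    """Keep one transcript per (locus, identical protein sequence) group.

    Priority: a multi-exon transcript whose intron chain exactly matches
    any reference transcript; then the largest ``n_samples``; remaining
    ties go to the lexicographically smallest transcript id.
    """
    ref_chains: set = set()
    for ref in ref_catalogs:
        ref_chains.update(ref.chain_index().keys())

    groups: dict[tuple[str, str], list[Transcript]] = {}
    for t in candidates.transcripts():
        protein = proteins.get(t.transcript_id)
        if protein is None:
            continue
        groups.setdefault((t.gene_id, protein.sequence), []).append(t)

    decisions: list[FilterDecision] = []
    for t in candidates.transcripts():
        if t.transcript_id not in proteins:
            decisions.append(FilterDecision(t.transcript_id, "dedup", "keep",
                                            "no_protein"))
    for (gene_id, _seq), members in groups.items():
        if len(members) == 1:
            decisions.append(FilterDecision(members[0].transcript_id, "dedup",
                                            "keep", "unique_protein"))
            continue

        def rank(t: Transcript) -> tuple:
            chain = intron_chain_of(t)
            ref_match = bool(chain) and chain in ref_chains
            return (not ref_match, -t.n_samples, t.transcript_id)

        ordered = sorted(members, key=rank)
        keeper = ordered[0]
        chain = intron_chain_of(keeper)
        why = ("matches_reference_chain"
               if chain and chain in ref_chains else "most_samples")
        decisions.append(FilterDecision(keeper.transcript_id, "dedup", "keep",
                                        why))
        for t in ordered[1:]:
            decisions.append(FilterDecision(
                t.transcript_id, "dedup", "drop",
                f"duplicate_of:{keeper.transcript_id}"))
    return _split(candidates, decisions), decisions


def readthrough_filter(candidates: Catalog, against: Catalog
                       ) -> tuple[Catalog, list[FilterDecision]]:
    """Drop candidates whose exons overlap exons of >= 2 same-strand loci.

    Overlap is exonic and strand-matched, so genes nested inside another
    gene's introns do not trigger removal, and antisense overlap never
    counts.  The candidate's own assigned locus counts as one.
    """
    trees = against.exon_trees()
    decisions: list[FilterDecision] = []
    for t in candidates.transcripts():
        tree = trees.get((t.chrom, t.strand))
        hit_genes: set[str] = set()
        if tree is not None:
            for exon in t.exons:
                for iv in tree.overlap(exon.start, exon.end + 1):
                    hit_genes.add(iv.data)
        if len(hit_genes) >= 2:
            decisions.append(FilterDecision(
                t.transcript_id, "readthrough", "drop",
                "readthrough:" + ",".join(sorted(hit_genes))))
        else:
            decisions.append(FilterDecision(t.transcript_id, "readthrough",
                                            "keep", "single_locus"))
    return _split(candidates, decisions), decisions


def assign_loci(candidates: Catalog, beta: Catalog) -> Catalog:
    """Give candidates lacking a beta gene id the beta gene they overlap most.

    Overlap is counted in exonic bases on the same strand.  Candidates
    with no exonic overlap keep their own gene id.
    """
    from dataclasses import replace

    trees = beta.exon_trees()
    out = Catalog(candidates.name)
    for t in candidates.transcripts():
        if t.gene_id in beta.genes:
            out.add(t)
            continue
        overlap: dict[str, int] = {}
        tree = trees.get((t.chrom, t.strand))
        if tree is not None:
            for exon in t.exons:
                for iv in tree.overlap(exon.start, exon.end + 1):
                    shared = (min(exon.end + 1, iv.end)
                              - max(exon.start, iv.begin))
                    overlap[iv.data] = overlap.get(iv.data, 0) + shared
        if overlap:
            best = sorted(overlap.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            out.add(replace(t, gene_id=best))
        else:
            out.add(t)
    return out


# ---------------------------------------------------------------------------
# Composition


@dataclass
class CascadeResult:
    survivors: Catalog
    merged: Catalog | None
    report: StageReport
    decisions: list[FilterDecision]

    def decisions_tsv(self) -> str:
        lines = ["transcript_id\tstage\taction\treason"]
        lines += [f"{d.transcript_id}\t{d.stage}\t{d.action}\t{d.reason}"
                  for d in self.decisions]
        return "\n".join(lines) + "\n"


def run_candidate_cascade(candidates: Catalog, beta: Catalog,
                          scores: StructureScoreTable,
                          config: CascadeConfig | None = None,
                          genome=None,
                          ref_catalogs: Sequence[Catalog] = (),
                          proteins: Mapping[str, ProteinRecord] | None = None,
                          beta_proteins: Mapping[str, ProteinRecord] | None = None,
                          disabled: Iterable[str] = ()
                          ) -> CascadeResult:
    """Screen candidates against the beta set and merge the survivors.

    Applies structure_gate -> substring -> containment -> fragment ->
    dedup -> readthrough in order.  ``proteins`` / ``beta_proteins`` may be
    precomputed; otherwise a genome is required to translate.  ``disabled``
    names stages to skip (used for order audits).  The returned
    :class:`CascadeResult` carries the surviving candidates, the merged
    catalog (beta plus survivors, ids unchanged), the stage report and the
    full decision log.
    """
    cfg = config or CascadeConfig()
    if proteins is None:
        if genome is None:
            raise CatalogError("need proteins or genome to run the cascade")
        proteins, _ = translate_catalog(candidates, genome)
    if beta_proteins is None:
        if genome is None:
            raise CatalogError("need beta_proteins or genome")
        beta_proteins, _ = translate_catalog(beta, genome)
    disabled = set(disabled)

    beta_locus = {t.transcript_id: t.gene_id for t in beta.transcripts()}
    stages = [
        ("structure_gate", lambda c: structure_gate(
            c, scores, cfg.plddt_threshold)),
        ("substring", lambda c: substring_filter(
            c, proteins, beta_proteins.values(),
            per_locus=cfg.substring_per_locus, beta_locus=beta_locus)),
        ("containment", lambda c: containment_resolution(
            c, proteins, beta, beta_proteins, scores)),
        ("fragment", lambda c: fragment_filter(
            c, proteins, cfg.min_protein_aa, cfg.fragment_fraction,
            beta=beta, beta_proteins=beta_proteins)),
        ("dedup", lambda c: dedup_identical(c, proteins, ref_catalogs)),
        ("readthrough", lambda c: readthrough_filter(c, beta)),
    ]

    report = StageReport()
    decisions: list[FilterDecision] = []
    current = candidates
    for stage_name, stage_fn in stages:
        if stage_name in disabled:
            continue
        n_in = len(current)
        current, stage_decisions = stage_fn(current)
        decisions.extend(stage_decisions)
        report.append(stage_name, n_in, len(current))

    merged = beta.copy(name=f"{beta.name}+{candidates.name}")
    for t in current.transcripts():
        merged.add(t)
    return CascadeResult(current, merged, report, decisions)


def run_full_cascade(candidates: Catalog, *, genome,
                     ref: Catalog, beta: Catalog,
                     scores: StructureScoreTable,
                     whitelist: Iterable[str] = (),
                     config: CascadeConfig | None = None,
                     ref_catalogs: Sequence[Catalog] | None = None,
                     disabled: Iterable[str] = ()) -> CascadeResult:
    """All nine stages: beta-set rules followed by the candidate cascade.

    ``ref`` supplies the trusted intron set (and the default dedup
    reference); ``beta`` the established protein set the candidates are
    screened against.
    """
    cfg = config or CascadeConfig()
    disabled = set(disabled)
    ref_catalogs = list(ref_catalogs) if ref_catalogs is not None else [ref]

    report = StageReport()
    decisions: list[FilterDecision] = []
    current = candidates

    proteins, _ = translate_catalog(candidates, genome)
    pre_stages = [
        ("orf_validity", lambda c: orf_validity_filter(c, genome)),
        ("intron_support", lambda c: intron_support_filter(
            c, ref, cfg.min_samples, genome)),
        ("truncation", lambda c: truncation_filter(
            c, proteins, whitelist, cfg.truncation_fraction)),
    ]
    for stage_name, stage_fn in pre_stages:
        if stage_name in disabled:
            continue
        n_in = len(current)
        current, stage_decisions = stage_fn(current)
        decisions.extend(stage_decisions)
        report.append(stage_name, n_in, len(current))

    beta_proteins, _ = translate_catalog(beta, genome)
    tail = run_candidate_cascade(
        current, beta, scores, cfg, genome=genome, ref_catalogs=ref_catalogs,
        proteins=proteins, beta_proteins=beta_proteins, disabled=disabled)
    for row in tail.report.rows:
        report.append(*row)
    decisions.extend(tail.decisions)
    return CascadeResult(tail.survivors, tail.merged, report, decisions)
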