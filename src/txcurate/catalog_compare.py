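"""Catalog comparison by exact intron-chain matching, plus census tools.

A pair of multi-exon transcripts is considered matching when their intron
chains are identical — every intron boundary agrees to the base.  On top of
that equivalence this module provides:

* :func:`match_catalogs` — one-way matching of a query catalog against a
  subject catalog;
* :func:`three_way_overlap` — the 7-region Venn partition of distinct
  intron chains across three catalogs;
* :func:`length_ratio_census` — per-gene min/max protein length ratios and
  counts of genes with extreme isoform-length variation;
* :func:`biotype_summary` — gene/transcript/distinct-protein counts per
  biotype;
* :func:`classify_as_events` — alternative-splicing events (exon skipping,
  intron retention, alternative translation start/stop) of a transcript
  against a canonical reference isoform;
* :func:`novel_isoform_screen` — novel, expression-dominant protein
  isoforms absent from a set of reference catalogs.

Single-exon transcripts have no intron chain; they match only when their
CDS genomic spans are identical (exon spans, for non-coding transcripts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annot_io import (
    Catalog,
    ProteinRecord,
    Transcript,
    intron_chain_of,
)

__all__ = [
    "MatchResult",
    "OverlapCounts",
    "ASEvent",
    "LengthRatioCensus",
    "match_catalogs",
    "three_way_overlap",
    "length_ratio_census",
    "biotype_summary",
    "classify_as_events",
    "novel_isoform_screen",
]


@dataclass(frozen=True)
class MatchResult:
    query_transcript_id: str
    subject_transcript_id: str | None
    status: str  # "exact_chain" | "single_exon_exact" | "none"


def _single_exon_key(t: Transcript) -> tuple:
    """Identity key for an intronless transcript: CDS span, else exon span."""
    if t.cds:
        return ("cds_span", t.chrom, t.strand, t.cds[0].start, t.cds[-1].end)
    return ("exon_span", t.chrom, t.strand, t.start, t.end)


def _chain_key(t: Transcript) -> tuple:
    """Equivalence key used by matching and Venn counting."""
    chain = intron_chain_of(t)
    if chain:
        return ("chain", chain)
    return ("single", _single_exon_key(t))


def match_catalogs(a: Catalog, b: Catalog) -> list[MatchResult]:
    """Match every transcript of ``a`` against ``b`` by intron chain.

    Multi-exon queries match on identical chrom+strand+intron chain;
    single-exon queries on identical CDS span (exon span if non-coding).
    When several subjects share a chain the lexicographically smallest
    subject id is reported.
    """
    subject_index: dict[tuple, str] = {}
    for t in b.transcripts():
        key = _chain_key(t)
        prev = subject_index.get(key)
        if prev is None or t.transcript_id < prev:
            subject_index[key] = t.transcript_id

    results: list[MatchResult] = []
    for t in a.transcripts():
        key = _chain_key(t)
        subject = subject_index.get(key)
        if subject is None:
            results.append(MatchResult(t.transcript_id, None, "none"))
        elif key[0] == "chain":
            results.append(MatchResult(t.transcript_id, subject,
                                       "exact_chain"))
        else:
            results.append(MatchResult(t.transcript_id, subject,
                                       "single_exon_exact"))
    return results


@dataclass
class OverlapCounts:
    """Distinct-chain counts for the 7 regions of a 3-catalog Venn."""

    regions: dict[str, int] = field(default_factory=dict)

    _ALL = ("a", "b", "c", "ab", "ac", "bc", "abc")

    def __post_init__(self) -> None:
        for region in self._ALL:
            self.regions.setdefault(region, 0)

    def __getitem__(self, region: str) -> int:
        return self.regions[region]

    @property
    def total(self) -> int:
        return sum(self.regions.values())


def three_way_overlap(a: Catalog, b: Catalog, c: Catalog,
                      coding_only: bool = False,
                      multi_exon_only: bool = False) -> OverlapCounts:
    """Partition distinct transcript equivalence keys into Venn regions.

    The counting unit is the distinct chain key, so duplicated chains
    within one catalog count once.  ``coding_only`` restricts to
    transcripts with a CDS; ``multi_exon_only`` drops intronless
    transcripts entirely (their matching rule is span-based, and whether
    to count them at all is a reporting choice).
    """

    def keys(catalog: Catalog) -> set[tuple]:
        out = set()
        for t in catalog.transcripts():
            if coding_only and not t.cds:
                continue
            key = _chain_key(t)
            if multi_exon_only and key[0] != "chain":
                continue
            out.add(key)
        return out

    ka, kb, kc = keys(a), keys(b), keys(c)
    counts = OverlapCounts()
    for key in ka | kb | kc:
        name = ""
        if key in ka:
            name += "a"
        if key in kb:
            name += "b"
        if key in kc:
            name += "c"
        counts.regions[name] += 1
    return counts


@dataclass
class LengthRatioCensus:
    """Per-gene protein length extremes and threshold counts.

    ``per_gene`` columns: gene_id, n_isoforms, min_aa, max_aa, ratio
    (min/max).  ``threshold_counts[t]`` is the number of multi-isoform
    genes whose shortest protein is strictly shorter than ``t`` times the
    longest — e.g. t=0.1 counts genes with a >=10-fold length spread.
    """

    per_gene: pd.DataFrame
    threshold_counts: dict[float, int]


def length_ratio_census(catalog: Catalog,
                        thresholds: Sequence[float] = (0.1, 0.2),
                        proteins: Mapping[str, ProteinRecord] | None = None,
                        lengths: Mapping[str, int] | None = None
                        ) -> LengthRatioCensus:
    """Census isoform length variation per gene.

    Protein lengths come from ``lengths`` (transcript_id -> aa), else from
    ``proteins``.  Genes with a single measured isoform are reported but
    excluded from threshold counts.
    """
    if lengths is None:
        if proteins is None:
            raise ValueError("need proteins or lengths")
        lengths = {tid: p.length_aa for tid, p in proteins.items()}

    rows = []
    for gene_id, transcripts in catalog.genes.items():
        aa = [lengths[t.transcript_id] for t in transcripts
              if t.transcript_id in lengths]
        if not aa:
            continue
        rows.append({
            "gene_id": gene_id,
            "n_isoforms": len(aa),
            "min_aa": min(aa),
            "max_aa": max(aa),
            "ratio": min(aa) / max(aa),
        })
    per_gene = pd.DataFrame(
        rows, columns=["gene_id", "n_isoforms", "min_aa", "max_aa", "ratio"])
    multi = per_gene[per_gene["n_isoforms"] >= 2]
    counts = {float(t): int((multi["min_aa"] < t * multi["max_aa"]).sum())
              for t in thresholds}
    return LengthRatioCensus(per_gene, counts)


def biotype_summary(catalog: Catalog,
                    proteins: Mapping[str, ProteinRecord] | None = None
                    ) -> pd.DataFrame:
    """Genes, transcripts and distinct proteins per biotype.

    A gene is counted under every biotype it has at least one transcript
    of.  Distinct proteins (exact string dedup) are reported where protein
    sequences are available, else left at 0.
    """
    rows: dict[str, dict] = {}
    for gene_id, transcripts in catalog.genes.items():
        seen_biotypes = set()
        for t in transcripts:
            row = rows.setdefault(t.biotype, {
                "biotype": t.biotype, "n_genes": 0, "n_transcripts": 0,
                "proteins": set()})
            row["n_transcripts"] += 1
            if t.biotype not in seen_biotypes:
                row["n_genes"] += 1
                seen_biotypes.add(t.biotype)
            if proteins and t.transcript_id in proteins:
                row["proteins"].add(proteins[t.transcript_id].sequence)
    records = [{"biotype": r["biotype"], "n_genes": r["n_genes"],
                "n_transcripts": r["n_transcripts"],
                "n_distinct_proteins": len(r["proteins"])}
               for r in sorted(rows.values(), key=lambda r: r["biotype"])]
    return pd.DataFrame(records, columns=[
        "biotype", "n_genes", "n_transcripts", "n_distinct_proteins"])


@dataclass(frozen=True)
class ASEvent:
    transcript_id: str
    event_type: str  # exon_skipping | intron_retention | alt_start | alt_stop
    chrom: str
    start: int
    end: int


def _cds_boundaries(t: Transcript) -> tuple[int, int] | None:
    """(5' start, 3' stop) genomic CDS boundary positions, strand-aware."""
    if not t.cds:
        return None
    if t.strand == "+":
        return t.cds[0].start, t.cds[-1].end
    return t.cds[-1].end, t.cds[0].start


def classify_as_events(t: Transcript, canon: Transcript) -> list[ASEvent]:
    """Alternative-splicing events of ``t`` measured against ``canon``.

    * ``exon_skipping``: an intron of ``t`` fully spans at least one
      complete canonical exon (event coordinates: the spanning intron).
    * ``intron_retention``: an exon of ``t`` fully contains a canonical
      intron plus at least 1 nt of both flanking canonical exons (event
      coordinates: the retained intron).
    * ``alt_start`` / ``alt_stop``: the genomic 5'/3' CDS boundary differs
      from the canonical one (only evaluated when both have a CDS).

    Events are deduplicated by coordinates.  A transcript identical to the
    canonical isoform yields no events.
    """
    if t.strand != canon.strand or t.chrom != canon.chrom:
        raise ValueError(
            f"{t.transcript_id} and {canon.transcript_id} are not on the "
            "same chrom/strand")

    events: set[ASEvent] = set()
    canon_introns = intron_chain_of(canon).introns

    for donor, acceptor in intron_chain_of(t).introns:
        skipped = [e for e in canon.exons
                   if donor <= e.start and e.end <= acceptor]
        if skipped:
            events.add(ASEvent(t.transcript_id, "exon_skipping",
                               t.chrom, donor, acceptor))

    for exon in t.exons:
        for donor, acceptor in canon_introns:
            if exon.start <= donor - 1 and acceptor + 1 <= exon.end:
                events.add(ASEvent(t.transcript_id, "intron_retention",
                                   t.chrom, donor, acceptor))

    mine, theirs = _cds_boundaries(t), _cds_boundaries(canon)
    if mine is not None and theirs is not None:
        if mine[0] != theirs[0]:
            events.add(ASEvent(t.transcript_id, "alt_start",
                               t.chrom, mine[0], mine[0]))
        if mine[1] != theirs[1]:
            events.add(ASEvent(t.transcript_id, "alt_stop",
                               t.chrom, mine[1], mine[1]))
    return sorted(events, key=lambda e: (e.event_type, e.start, e.end))


def novel_isoform_screen(catalog: Catalog,
                         refs: Sequence[Catalog],
                         proteins: Mapping[str, ProteinRecord],
                         ref_proteins: Iterable[ProteinRecord] = (),
                         min_tpm: float = 1000.0,
                         min_fraction: float = 0.5) -> list[str]:
    """Novel, highly expressed, expression-dominant protein isoforms.

    Selects multi-exon coding transcripts that (i) have no exact-chain
    match in any reference catalog, (ii) encode a protein not identical to
    any reference protein, (iii) have cumulative TPM strictly above
    ``min_tpm``, and (iv) account for more than ``min_fraction`` of the
    summed TPM of their gene's transcripts.
    """
    ref_chains: set = set()
    for ref in refs:
        ref_chains.update(ref.chain_index().keys())
    ref_seqs = {p.sequence for p in ref_proteins}

    gene_tpm = {gene_id: sum(t.tpm_total for t in transcripts)
                for gene_id, transcripts in catalog.genes.items()}

    selected: list[str] = []
    for t in catalog.transcripts():
        if not t.is_coding:
            continue
        chain = intron_chain_of(t)
        if not chain:
            continue
        protein = proteins.get(t.transcript_id)
        if protein is None:
            continue
        if chain in ref_chains:
            continue
        if protein.sequence in ref_seqs:
            continue
        if not t.tpm_total > min_tpm:
            continue
        if not t.tpm_total > min_fraction * gene_tpm[t.gene_id]:
            continue
        selected.append(t.transcript_id)
    return sorted(selected)
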