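"""Deterministic synthetic data so every module is testable offline.

The generators here emulate the *inputs* of a large expression-driven
annotation build at desk scale: a toy genome, transcript catalogs with
planted defect classes (invalid ORFs, unsupported novel introns, truncated
isoforms, low-confidence structures, substring/duplicate proteins,
read-through artifacts), a reference annotation, an established "beta"
protein set, structure-score and expression-support tables, and a multiple
whole-genome alignment realizing a chosen splice-site conservation plan.

Every generator is a pure function of a :class:`FixtureSpec` (or explicit
arguments) and a seed: the same seed yields byte-identical outputs.  All
outputs are standard formats (FASTA / GTF / TSV / MAF), so fixtures double
as end-to-end exercises of the real parsers.

Design notes on realism: each transcript occupies its own genomic block
with a back-translated CDS stamped into a random background, so proteins
and splice boundaries are exact by construction.  That gives full control
over which cascade stage removes which transcript, at the cost of
isoforms of one gene not sharing genomic sequence — the fixtures model the
*bookkeeping* of curation, not the biology of overlapping isoforms.

The module also packages a handful of published worked-example inputs
(the Titin isoform length table, the MANE v1.0 summary counts, the GP6
spliced-read support counts and example structure-confidence scores) used
by the documentation and the acceptance checks.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annot_io import (
    Catalog,
    GenomeInterval,
    Transcript,
    write_gtf,
)
from .conservation import MafBlock, MafRow
from .filter_cascade import StructureScoreTable

__all__ = [
    "FixtureSpec",
    "FixtureBundle",
    "make_genome",
    "make_catalog",
    "make_bundle",
    "make_maf",
    "make_venn_catalogs",
    "make_orf_assign_fixture",
    "make_conservation_fixture",
    "write_fasta",
    "write_maf",
    "write_support_tsv",
    "write_scores_tsv",
    "write_truth_tsv",
    "write_bundle",
    "ttn_isoform_lengths",
    "TTN_SHORT_FUNCTIONAL_ISOFORM",
    "MANE_V1_COUNTS",
    "GP6_SPLICED_READS",
    "EXAMPLE_PLDDT_SCORES",
    "DEFAULT_PLANTED_DEFECTS",
    "DEFAULT_MAF_SPECIES",
]

# ---------------------------------------------------------------------------
# Published worked-example inputs

#: MANE v1.0 summary: one transcript per protein-coding gene plus a small
#: set of extra transcripts carried for clinical significance.
MANE_V1_COUNTS = {"transcripts": 19120, "proteins": 19062}

#: Spliced-read support for the two competing last introns of GP6: the
#: longer intron (used by the alternative isoforms) versus the shorter
#: intron used by the canonical (MANE) isoform.
GP6_SPLICED_READS = {"long_intron": 15254, "short_intron": 1177}

#: Mean pLDDT scores from the GP6/TMEM11 worked examples: the canonical
#: GP6 protein is largely disordered (49.3) while the alternative isoform
#: is confident (74.5); for TMEM11 the alternative isoform (78.6) also
#: outscores the canonical protein (68.3).
EXAMPLE_PLDDT_SCORES = {
    "GP6_canonical": 49.3,
    "GP6_alternative": 74.5,
    "TMEM11_alternative": 78.6,
    "TMEM11_canonical": 68.3,
}

#: The 5604aa Titin isoform with experimental evidence of function; the
#: standard whitelist entry for the truncation filter's worked example.
TTN_SHORT_FUNCTIONAL_ISOFORM = "ENST00000360870.10"


def ttn_isoform_lengths() -> dict[str, int]:
    """The packaged Titin (TTN) isoform table: transcript id -> protein aa.

    Fifteen annotated isoforms ranging from 48 to 35,991 amino acids; the
    classic worked example for the truncation rule.
    """
    text = (resources.files("txcurate") / "data" / "ttn_isoforms.tsv"
            ).read_text()
    lengths: dict[str, int] = {}
    for line in text.splitlines()[1:]:
        if line:
            tid, aa, _shared = line.split("\t")
            lengths[tid] = int(aa)
    return lengths


def ttn_catalog() -> Catalog:
    """The TTN table as a single-gene catalog (one exon per transcript)."""
    catalog = Catalog("ttn")
    for i, (tid, aa) in enumerate(sorted(ttn_isoform_lengths().items())):
        start = 1 + i * 200000
        exon = GenomeInterval("chr2", start, start + 3 * (aa + 1) + 47, "-")
        catalog.add(Transcript(tid, "TTN", exons=(exon,),
                               biotype="protein_coding"))
    return catalog


# ---------------------------------------------------------------------------
# Spec

#: Planted defect counts used by the default recovery fixture: one planted
#: transcript class per cascade stage, among 200 candidates.
DEFAULT_PLANTED_DEFECTS = {
    "invalid_orf": 7,
    "unsupported_intron": 6,
    "truncated": 5,
    "low_plddt": 10,
    "substring": 6,
    "duplicate_protein": 4,
    "readthrough": 3,
}

#: A 30-species alignment panel: 27 primates (reference first) plus mouse,
#: dog and armadillo.
DEFAULT_MAF_SPECIES = tuple(
    ["hg38", "panTro", "gorGor"]
    + [f"primate{i:02d}" for i in range(1, 25)]
    + ["mm10", "canFam", "dasNov"]
)


@dataclass
class FixtureSpec:
    """Everything the generators need, in one deterministic recipe.

    ``isoforms_per_gene`` is a (low, high) inclusive range sampled
    uniformly; with the defaults the catalog averages five isoforms per
    gene.  ``conservation_plan`` is an ordered sequence of
    ``(n_introns, preserved_species)`` groups applied to the catalog's
    distinct introns in genomic order.
    """

    seed: int = 1
    n_genes: int = 40
    n_transcripts: int | None = 200
    isoforms_per_gene: tuple[int, int] = (2, 8)
    planted_defects: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_DEFECTS))
    maf_species: tuple[str, ...] = DEFAULT_MAF_SPECIES
    ref_species: str = "hg38"
    conservation_plan: tuple[tuple[int, tuple[str, ...]], ...] | None = None
    chrom: str = "chrT"
    protein_aa: int = 100
    minus_strand_every: int = 3   # every k-th gene goes on the minus strand

    def __post_init__(self) -> None:
        unknown = set(self.planted_defects) - set(DEFAULT_PLANTED_DEFECTS)
        if unknown:
            raise ValueError(f"unknown defect classes: {sorted(unknown)}")
        if self.maf_species and self.ref_species != self.maf_species[0]:
            raise ValueError("ref_species must be first in maf_species")


@dataclass
class FixtureBundle:
    """All artifacts of one synthetic build, plus the planted truth."""

    spec: FixtureSpec
    genome: dict[str, str]
    candidates: Catalog
    ref: Catalog
    beta: Catalog
    scores: StructureScoreTable
    support: dict[str, tuple[float, int]]
    truth: dict[str, str]   # transcript_id -> defect class or "clean"
    whitelist: frozenset[str] = frozenset()


# ---------------------------------------------------------------------------
# Sequence-level helpers

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "*": "TAA",
}
_COMP = str.maketrans("ACGT", "TGCA")


def _backtranslate(protein: str) -> str:
    """One fixed codon per amino acid; appends a stop codon."""
    return "".join(_CODON[aa] for aa in protein) + _CODON["*"]


def _random_protein(rng: random.Random, length: int,
                    seen: set[str]) -> str:
    while True:
        protein = "M" + "".join(rng.choice(_AA) for _ in range(length - 1))
        if protein not in seen:
            seen.add(protein)
            return protein


class _GenomeBuilder:
    """Allocates disjoint blocks on a chromosome and stamps exact bases."""

    def __init__(self, rng: random.Random, chrom: str):
        self.rng = rng
        self.chrom = chrom
        self.cursor = 1
        self.stamps: dict[int, str] = {}

    def alloc(self, length: int, gap: int = 50) -> int:
        start = self.cursor
        self.cursor += length + gap
        return start

    def stamp(self, pos: int, bases: str) -> None:
        for i, base in enumerate(bases):
            self.stamps[pos + i] = base

    def build(self, margin: int = 100) -> str:
        n = self.cursor + margin
        seq = [self.rng.choice("ACGT") for _ in range(n)]
        for pos, base in self.stamps.items():
            seq[pos - 1] = base
        return "".join(seq)


def _design_transcript(builder: _GenomeBuilder, tid: str, gid: str,
                       protein: str | None, *, strand: str = "+",
                       n_exons: int = 3, utr5: int = 24, utr3: int = 24,
                       intron_len: int = 90, exonic_len: int | None = None,
                       donor: str = "GT", acceptor: str = "AG",
                       biotype: str = "protein_coding") -> Transcript:
    """Lay out one transcript in its own block and stamp its sequence.

    When ``protein`` is given its back-translated CDS (stop included) is
    stamped into the exons so translation recovers the protein exactly;
    intron boundaries are stamped with ``donor``/``acceptor`` motifs in
    transcript orientation.  ``protein`` may contain ``*`` to plant an
    internal stop codon (an invalid ORF).
    """
    if protein:
        cds_nt = "".join(_CODON[aa] for aa in protein) + _CODON["*"]
        exonic = utr5 + len(cds_nt) + utr3
    else:
        cds_nt = ""
        exonic = exonic_len or (utr5 + utr3 + 60)
    per_exon = [exonic // n_exons] * n_exons
    per_exon[-1] += exonic - sum(per_exon)

    span = exonic + (n_exons - 1) * intron_len
    start = builder.alloc(span)

    exons: list[GenomeInterval] = []
    pos = start
    for elen in per_exon:
        exons.append(GenomeInterval(builder.chrom, pos, pos + elen - 1, strand))
        pos += elen + intron_len

    # stamp intron boundary motifs in transcript orientation
    rc = lambda s: s.translate(_COMP)[::-1]
    for left, right in zip(exons, exons[1:]):
        d, a = left.end + 1, right.start - 1
        if strand == "+":
            builder.stamp(d, donor)
            builder.stamp(a - 1, acceptor)
        else:
            builder.stamp(d, rc(acceptor))
            builder.stamp(a - 1, rc(donor))

    cds: tuple[GenomeInterval, ...] = ()
    if protein:
        # genomic positions of exonic bases in transcript (5'->3') order
        tx_positions: list[int] = []
        ordered = exons if strand == "+" else list(reversed(exons))
        for exon in ordered:
            rng_pos = range(exon.start, exon.end + 1)
            tx_positions.extend(rng_pos if strand == "+" else reversed(rng_pos))
        cds_positions = tx_positions[utr5 : utr5 + len(cds_nt)]
        for tx_pos, base in zip(cds_positions, cds_nt):
            builder.stamp(tx_pos, base if strand == "+"
                          else base.translate(_COMP))
        # group consecutive genomic positions into CDS segments
        sorted_pos = sorted(cds_positions)
        segments: list[GenomeInterval] = []
        seg_start = prev = sorted_pos[0]
        for p in sorted_pos[1:]:
            if p != prev + 1:
                segments.append(GenomeInterval(builder.chrom, seg_start, prev,
                                               strand))
                seg_start = p
            prev = p
        segments.append(GenomeInterval(builder.chrom, seg_start, prev, strand))
        cds = tuple(segments)

    return Transcript(tid, gid, exons=tuple(exons), cds=cds, biotype=biotype)


# ---------------------------------------------------------------------------
# The defect bundle


def make_bundle(spec: FixtureSpec) -> FixtureBundle:
    """Build the full synthetic curation scenario for ``spec``.

    Produces candidates with planted defect classes, a reference catalog
    containing twins of every candidate whose introns should count as
    trusted, a beta catalog (one established protein per gene, plus the
    gene pairs that read-through candidates span), score and support
    tables, and the truth table mapping each candidate to its class.
    """
    rng = random.Random(spec.seed)
    builder = _GenomeBuilder(rng, spec.chrom)
    defects = dict(spec.planted_defects)
    n_readthrough = defects.pop("readthrough", 0)

    # --- gene sizes -------------------------------------------------------
    total = spec.n_transcripts
    if total is None:
        sizes = [rng.randint(*spec.isoforms_per_gene)
                 for _ in range(spec.n_genes)]
    else:
        budget = total - n_readthrough
        if budget < spec.n_genes:
            raise ValueError("n_transcripts too small for n_genes")
        sizes = []
        for i in range(spec.n_genes):
            remaining_genes = spec.n_genes - i - 1
            low, high = spec.isoforms_per_gene
            lo = max(low, budget - remaining_genes * high)
            hi = min(high, budget - remaining_genes * low)
            size = rng.randint(lo, hi) if lo <= hi else max(1, budget)
            sizes.append(size)
            budget -= size
        if budget:
            sizes[-1] += budget

    # --- class assignment -------------------------------------------------
    # slot map: (gene index, slot index) -> class; constrained classes first
    slot_class: dict[tuple[int, int], str] = {}
    keeper_of: dict[tuple[int, int], tuple[int, int]] = {}
    free: dict[int, list[int]] = {gi: list(range(sz))
                                  for gi, sz in enumerate(sizes)}

    def take(gi: int) -> tuple[int, int]:
        return (gi, free[gi].pop(0))

    multi = [gi for gi, sz in enumerate(sizes) if sz >= 2]
    cursor = 0
    for _ in range(defects.pop("duplicate_protein", 0)):
        while len(free[multi[cursor % len(multi)]]) < 2:
            cursor += 1
        gi = multi[cursor % len(multi)]
        cursor += 1
        dup, keeper = take(gi), take(gi)
        slot_class[dup] = "duplicate_protein"
        slot_class[keeper] = "clean"        # reserved keeper
        keeper_of[dup] = keeper
    for _ in range(defects.pop("truncated", 0)):
        while len(free[multi[cursor % len(multi)]]) < 2:
            cursor += 1
        gi = multi[cursor % len(multi)]
        cursor += 1
        slot_class[take(gi)] = "truncated"
        slot_class[take(gi)] = "clean"      # companion defines the locus max
    flat = [(gi, si) for gi in range(len(sizes)) for si in free[gi]]
    flat_iter = iter(flat)
    for cls in ("invalid_orf", "unsupported_intron", "low_plddt", "substring"):
        for _ in range(defects.pop(cls, 0)):
            try:
                slot_class[next(flat_iter)] = cls
            except StopIteration:
                raise ValueError("not enough transcripts for planted defects")
    for slot in flat_iter:
        slot_class[slot] = "clean"

    # --- build genes ------------------------------------------------------
    seen_proteins: set[str] = set()
    candidates = Catalog("candidates")
    ref = Catalog("reference")
    beta = Catalog("beta")
    scores = StructureScoreTable()
    support: dict[str, tuple[float, int]] = {}
    truth: dict[str, str] = {}
    aa = spec.protein_aa

    for gi, size in enumerate(sizes):
        gid = f"G{gi:03d}"
        strand = "-" if (spec.minus_strand_every
                         and gi % spec.minus_strand_every == 0) else "+"
        beta_protein = _random_protein(rng, aa, seen_proteins)
        beta_t = _design_transcript(builder, f"BETA_{gid}", gid, beta_protein,
                                    strand=strand, n_exons=1)
        beta.add(beta_t)
        scores[beta_t.transcript_id] = round(rng.uniform(72.0, 92.0), 1)

        for si in range(size):
            cls = slot_class[(gi, si)]
            tid = f"TX{gi:03d}.{si}"
            truth[tid] = cls
            n_samples, tpm = 20, round(rng.uniform(10.0, 500.0), 2)
            score = round(rng.uniform(71.0, 95.0), 1)
            has_ref_twin = True

            if cls == "clean":
                protein = _random_protein(rng, aa, seen_proteins)
                if (gi, si) in keeper_of.values():
                    n_samples = 40   # the keeper of a duplicate pair
            elif cls == "duplicate_protein":
                # placeholder protein; re-stamped below with the keeper's
                protein = _random_protein(rng, aa, seen_proteins)
                n_samples = 5
            elif cls == "truncated":
                protein = _random_protein(rng, max(2, aa // 8), seen_proteins)
            elif cls == "invalid_orf":
                base = _random_protein(rng, aa, seen_proteins)
                protein = base[: aa // 2] + "*" + base[aa // 2 + 1 :]
            elif cls == "low_plddt":
                protein = _random_protein(rng, aa, seen_proteins)
                score = round(rng.uniform(40.0, 62.0), 1)
            elif cls == "substring":
                protein = beta_protein[: aa - 20 - si]
                seen_proteins.add(protein)
            elif cls == "unsupported_intron":
                protein = _random_protein(rng, aa, seen_proteins)
                n_samples = 1
                has_ref_twin = False
            else:  # pragma: no cover
                raise AssertionError(cls)

            t = _design_transcript(builder, tid, gid, protein, strand=strand)
            t = replace(t, n_samples=n_samples, tpm_total=tpm)
            candidates.add(t)
            scores[tid] = score
            support[tid] = (tpm, n_samples)
            if has_ref_twin:
                ref.add(replace(t, transcript_id=f"REF_{tid}",
                                gene_id=f"REF_{gid}", n_samples=0,
                                tpm_total=0.0))

    # fix duplicate pairs where the planted copy was built before its keeper
    rebuilt: list[tuple[str, str]] = []
    for dup_slot, keeper_slot in keeper_of.items():
        dup_tid = f"TX{dup_slot[0]:03d}.{dup_slot[1]}"
        keeper_tid = f"TX{keeper_slot[0]:03d}.{keeper_slot[1]}"
        rebuilt.append((dup_tid, keeper_tid))
    _align_duplicate_proteins(builder, candidates, ref, rebuilt)

    # --- read-through artifacts ------------------------------------------
    for ri in range(n_readthrough):
        _plant_readthrough(builder, rng, spec, ri, seen_proteins, candidates,
                           beta, scores, support, truth)

    genome = {spec.chrom: builder.build()}
    return FixtureBundle(spec=spec, genome=genome, candidates=candidates,
                         ref=ref, beta=beta, scores=scores, support=support,
                         truth=truth)


def _align_duplicate_proteins(builder: _GenomeBuilder, candidates: Catalog,
                              ref: Catalog,
                              pairs: list[tuple[str, str]]) -> None:
    """Re-stamp each planted duplicate's CDS with its keeper's protein."""
    for dup_tid, keeper_tid in pairs:
        keeper = candidates[keeper_tid]
        dup = candidates[dup_tid]
        # read the keeper's CDS nucleotide sequence from the stamps
        keeper_nt = _stamped_cds_nt(builder, keeper)
        _restamp_cds(builder, dup, keeper_nt)


def _cds_tx_positions(t: Transcript) -> list[int]:
    """Genomic positions of CDS bases in transcript (5'->3') order."""
    ordered = t.cds if t.strand == "+" else tuple(reversed(t.cds))
    positions: list[int] = []
    for seg in ordered:
        rng_pos = range(seg.start, seg.end + 1)
        positions.extend(rng_pos if t.strand == "+" else reversed(rng_pos))
    return positions


def _stamped_cds_nt(builder: _GenomeBuilder, t: Transcript) -> str:
    out = []
    for pos in _cds_tx_positions(t):
        base = builder.stamps[pos]
        out.append(base if t.strand == "+" else base.translate(_COMP))
    return "".join(out)


def _restamp_cds(builder: _GenomeBuilder, t: Transcript, cds_nt: str) -> None:
    positions = _cds_tx_positions(t)
    if len(positions) != len(cds_nt):
        raise ValueError("CDS length mismatch while planting duplicate")
    for pos, base in zip(positions, cds_nt):
        builder.stamp(pos, base if t.strand == "+"
                      else base.translate(_COMP))


def _plant_readthrough(builder: _GenomeBuilder, rng: random.Random,
                       spec: FixtureSpec, index: int,
                       seen_proteins: set[str],
                       candidates: Catalog, beta: Catalog,
                       scores: StructureScoreTable,
                       support: dict[str, tuple[float, int]],
                       truth: dict[str, str]) -> None:
    """One read-through candidate spanning exons of two beta genes.

    Layout (plus strand; all coordinates relative to the block start)::

        beta A  exon 1..400,    CDS  50..352
        cand    exon 360..459,  intron 460..539 (GT/AG), exon 540..939
                CDS 380..459 + 540..762
        beta B  exon 600..1300, CDS 960..1262

    The candidate's exons overlap exons of both beta genes on the same
    strand, but no CDS regions collide, so all three proteins are exact.
    """
    aa = spec.protein_aa
    chrom = spec.chrom
    o = builder.alloc(1400)

    gid_a, gid_b = f"GR{index}a", f"GR{index}b"
    protein_a = _random_protein(rng, aa, seen_proteins)
    protein_b = _random_protein(rng, aa, seen_proteins)
    protein_rt = _random_protein(rng, aa, seen_proteins)
    nt_a = _backtranslate(protein_a)
    nt_b = _backtranslate(protein_b)
    nt_rt = _backtranslate(protein_rt)
    assert len(nt_a) == 303

    beta_a = Transcript(f"BETA_{gid_a}", gid_a,
                        exons=(GenomeInterval(chrom, o, o + 399, "+"),),
                        cds=(GenomeInterval(chrom, o + 49, o + 351, "+"),),
                        biotype="protein_coding")
    beta_b = Transcript(f"BETA_{gid_b}", gid_b,
                        exons=(GenomeInterval(chrom, o + 599, o + 1299, "+"),),
                        cds=(GenomeInterval(chrom, o + 959, o + 1261, "+"),),
                        biotype="protein_coding")
    builder.stamp(o + 49, nt_a)
    builder.stamp(o + 959, nt_b)

    tid = f"RT{index:02d}"
    cand = Transcript(
        tid, gid_a,
        exons=(GenomeInterval(chrom, o + 359, o + 458, "+"),
               GenomeInterval(chrom, o + 539, o + 938, "+")),
        cds=(GenomeInterval(chrom, o + 379, o + 458, "+"),
             GenomeInterval(chrom, o + 539, o + 761, "+")),
        biotype="protein_coding")
    builder.stamp(o + 379, nt_rt[:80])
    builder.stamp(o + 539, nt_rt[80:])
    builder.stamp(o + 459, "GT")
    builder.stamp(o + 537, "AG")

    beta.add(beta_a)
    beta.add(beta_b)
    candidates.add(replace(cand, n_samples=20,
                           tpm_total=round(rng.uniform(10.0, 500.0), 2)))
    truth[tid] = "readthrough"
    scores[tid] = round(rng.uniform(71.0, 95.0), 1)
    scores[beta_a.transcript_id] = round(rng.uniform(72.0, 92.0), 1)
    scores[beta_b.transcript_id] = round(rng.uniform(72.0, 92.0), 1)
    support[tid] = (candidates[tid].tpm_total, 20)


def make_genome(spec: FixtureSpec) -> dict[str, str]:
    """The genome of :func:`make_bundle` for ``spec`` (same seed, same bytes)."""
    return make_bundle(spec).genome


def make_catalog(spec: FixtureSpec, genome: Mapping[str, str] | None = None
                 ) -> tuple[Catalog, dict[str, str]]:
    """The candidate catalog and truth table of :func:`make_bundle`.

    ``genome`` is accepted so callers can pass the output of
    :func:`make_genome`; the design is fully determined by ``spec.seed``,
    and a mismatched genome is rejected.
    """
    bundle = make_bundle(spec)
    if genome is not None and dict(genome) != bundle.genome:
        raise ValueError("genome does not match spec (different seed?)")
    return bundle.candidates, bundle.truth


# ---------------------------------------------------------------------------
# Venn fixture


def make_venn_catalogs(region_sizes: Mapping[str, int], seed: int = 1
                       ) -> tuple[Catalog, Catalog, Catalog]:
    """Three catalogs whose 3-way chain Venn has the given region sizes.

    ``region_sizes`` keys are the regions ``a,b,c,ab,ac,bc,abc``; each
    planted chain is unique, two-intron, and shared by exactly the member
    catalogs of its region.
    """
    rng = random.Random(seed)
    catalogs = {"a": Catalog("A"), "b": Catalog("B"), "c": Catalog("C")}
    base = 1
    counter = 0
    for region in ("abc", "ab", "ac", "bc", "a", "b", "c"):
        for i in range(region_sizes.get(region, 0)):
            jitter = rng.randint(0, 20)  # distinct chains, seeded layout
            exons = tuple(
                GenomeInterval("chrV", base + k * 200 + (k > 0) * jitter,
                               base + k * 200 + (k > 0) * jitter + 99, "+")
                for k in range(3))
            for member in region:
                catalogs[member].add(Transcript(
                    f"{member.upper()}_{region}_{i}", f"GV{counter}",
                    exons=exons, biotype="protein_coding"))
            base += 1000
            counter += 1
    return catalogs["a"], catalogs["b"], catalogs["c"]


# ---------------------------------------------------------------------------
# ORF-assignment fixture


def make_orf_assign_fixture(seed: int = 1, n_projectable: int = 10,
                            n_fallback: int = 5
                            ) -> tuple[dict[str, str], Catalog, Catalog]:
    """(genome, catalog, reference) with known CDS-assignment outcomes.

    ``n_projectable`` transcripts share their reference twin's intron
    chain (wider UTR exons) so reference projection succeeds exactly;
    ``n_fallback`` transcripts retain their reference's CDS-internal
    intron, breaking projection, but carry a planted ATG..stop ORF inside
    the retained intron for the longest-ORF fallback to find.
    """
    rng = random.Random(seed)
    builder = _GenomeBuilder(rng, "chrO")
    seen: set[str] = set()
    catalog = Catalog("query")
    ref = Catalog("reference")

    for i in range(n_projectable):
        protein = _random_protein(rng, 40, seen)
        r = _design_transcript(builder, f"R{i}", f"OG{i}", protein, n_exons=2)
        ref.add(r)
        wider = (GenomeInterval(r.chrom, r.exons[0].start, r.exons[0].end,
                                r.strand),
                 GenomeInterval(r.chrom, r.exons[1].start, r.exons[1].end + 12,
                                r.strand))
        catalog.add(Transcript(f"T{i}", f"OG{i}", exons=wider,
                               biotype="protein_coding"))
    for i in range(n_fallback):
        protein = _random_protein(rng, 40, seen)
        r = _design_transcript(builder, f"RF{i}", f"OGF{i}", protein,
                               n_exons=2, intron_len=160)
        ref.add(r)
        # single exon spanning the whole locus: the CDS-internal intron is
        # retained, so projection fails with cds_intron_broken
        merged = (GenomeInterval(r.chrom, r.start, r.end, r.strand),)
        catalog.add(Transcript(f"TF{i}", f"OGF{i}", exons=merged,
                               biotype="protein_coding"))
        # plant a fallback ORF inside the retained intron
        orf_protein = _random_protein(rng, 30, seen)
        intron_start = r.exons[0].end + 1
        builder.stamp(intron_start + 20, _backtranslate(orf_protein))

    return {"chrO": builder.build()}, catalog, ref


# ---------------------------------------------------------------------------
# Conservation fixtures


def make_conservation_fixture(spec: FixtureSpec
                              ) -> tuple[dict[str, str], Catalog,
                                         list[MafBlock]]:
    """Genome, intron-bearing catalog and MAF realizing the conservation plan.

    The catalog has one two-exon transcript per planned intron (biotype
    ``lncRNA``, the class whose conservation profile is worth histogramming
    separately); the MAF preserves each intron's GT/AG boundaries in
    exactly the species subset the plan names.
    """
    if spec.conservation_plan is None:
        raise ValueError("spec.conservation_plan is required")
    rng = random.Random(spec.seed)
    builder = _GenomeBuilder(rng, spec.chrom)
    catalog = Catalog("lncrna")
    plan_per_intron: list[tuple[str, ...]] = []
    idx = 0
    for count, preserved in spec.conservation_plan:
        for _ in range(count):
            strand = "-" if (spec.minus_strand_every and
                             idx % spec.minus_strand_every == 0) else "+"
            t = _design_transcript(builder, f"L{idx:03d}", f"LG{idx:03d}",
                                   None, strand=strand, n_exons=2,
                                   exonic_len=80, intron_len=60,
                                   biotype="lncRNA")
            catalog.add(t)
            plan_per_intron.append(tuple(preserved))
            idx += 1
    genome = {spec.chrom: builder.build()}
    blocks = make_maf(spec, genome, catalog,
                      plan_per_intron=plan_per_intron)
    return genome, catalog, blocks


def make_maf(spec: FixtureSpec, genome: Mapping[str, str], catalog: Catalog,
             plan_per_intron: Sequence[tuple[str, ...]] | None = None,
             n_blocks_per_chrom: int = 2,
             gapped_species: Iterable[str] = ()) -> list[MafBlock]:
    """A multiple alignment whose boundary dinucleotides realize the plan.

    The reference row is the fixture genome; every other species' sequence
    is the reference with all four boundary bases of each *non-preserved*
    intron substituted (to C, which is non-consensus in either reading
    orientation).  Species in ``gapped_species`` get gaps at those columns
    instead.  Introns are taken in sorted genomic order; the plan must
    cover all distinct introns of the catalog.
    """
    from .annot_io import intron_chain_of

    introns: set[tuple[str, int, int, str]] = set()
    for t in catalog.transcripts():
        chain = intron_chain_of(t)
        for donor, acceptor in chain.introns:
            introns.add((chain.chrom, donor, acceptor, chain.strand))
    ordered = sorted(introns)

    if plan_per_intron is None:
        if spec.conservation_plan is not None:
            plan_per_intron = []
            for count, preserved in spec.conservation_plan:
                plan_per_intron.extend([tuple(preserved)] * count)
        else:
            plan_per_intron = [tuple(spec.maf_species)] * len(ordered)
    if len(plan_per_intron) != len(ordered):
        raise ValueError(
            f"conservation plan covers {len(plan_per_intron)} introns, "
            f"catalog has {len(ordered)}")

    gapped = set(gapped_species)
    species = list(spec.maf_species)
    ref_sp = spec.ref_species

    # per-species, per-chrom sequence with substitutions/gaps applied
    seqs: dict[str, dict[str, list[str]]] = {
        sp: {chrom: list(seq.upper()) for chrom, seq in genome.items()}
        for sp in species}
    for (chrom, donor, acceptor, _strand), preserved in zip(
            ordered, plan_per_intron):
        for sp in species:
            if sp == ref_sp or (sp in preserved and sp not in gapped):
                continue
            fill = "-" if sp in gapped else "C"
            for pos in (donor, donor + 1, acceptor - 1, acceptor):
                seqs[sp][chrom][pos - 1] = fill

    blocks: list[MafBlock] = []
    for chrom, ref_seq in genome.items():
        length = len(ref_seq)
        src_sizes = {sp: length - seqs[sp][chrom].count("-")
                     for sp in species}
        bounds = [round(k * length / n_blocks_per_chrom)
                  for k in range(n_blocks_per_chrom + 1)]
        consumed = {sp: 0 for sp in species}
        for lo, hi in zip(bounds, bounds[1:]):
            rows = []
            for sp in species:
                text = "".join(seqs[sp][chrom][lo:hi])
                size = len(text) - text.count("-")
                rows.append(MafRow(src=f"{sp}.{chrom}", start=consumed[sp],
                                   size=size, strand="+",
                                   src_size=src_sizes[sp], text=text))
                consumed[sp] += size
            blocks.append(MafBlock(tuple(rows)))
    return blocks


# ---------------------------------------------------------------------------
# Writers (all plain text)


def write_fasta(genome: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_maf(blocks: Iterable[MafBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1 scoring=none\n")
        for block in blocks:
            fh.write("a score=0.0\n")
            for row in block.rows:
                fh.write(f"s {row.src} {row.start} {row.size} {row.strand} "
                         f"{row.src_size} {row.text}\n")
            fh.write("\n")


def write_support_tsv(support: Mapping[str, tuple[float, int]],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\ttpm_total\tn_samples\n")
        for tid in sorted(support):
            tpm, n = support[tid]
            fh.write(f"{tid}\t{tpm}\t{n}\n")


def write_scores_tsv(scores: StructureScoreTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tmean_plddt\n")
        for pid, value in sorted(scores.items()):
            fh.write(f"{pid}\t{value}\n")


def write_truth_tsv(truth: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tclass\n")
        for tid in sorted(truth):
            fh.write(f"{tid}\t{truth[tid]}\n")


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every artifact of a bundle as standard files; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out / "genome.fa",
        "candidates": out / "candidates.gtf",
        "ref": out / "reference.gtf",
        "beta": out / "beta.gtf",
        "scores": out / "plddt.tsv",
        "support": out / "support.tsv",
        "truth": out / "truth.tsv",
    }
    write_fasta(bundle.genome, paths["genome"])
    write_gtf(bundle.candidates, paths["candidates"])
    write_gtf(bundle.ref, paths["ref"])
    write_gtf(bundle.beta, paths["beta"])
    write_scores_tsv(bundle.scores, paths["scores"])
    write_support_tsv(bundle.support, paths["support"])
    write_truth_tsv(bundle.truth, paths["truth"])
    return paths
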