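"""Splice-site conservation counting in whole-genome multiple alignments.

For every intron of a catalog this module asks how many species in a MAF
multiple alignment preserve the consensus splice-site dinucleotides — GT
at the donor (5') end and AG at the acceptor (3') end, read in transcript
orientation.  Only the four boundary columns of each intron are mapped
through the alignment, so introns whose bodies span several alignment
blocks are handled naturally.  A species with a gap, or with no aligned
row, at any of the four columns preserves nothing and is not counted.

Conservation of intron boundaries behaves very differently between gene
classes: protein-coding introns tend to keep GT/AG across deep mammalian
clades, while many lncRNA introns are intact only within a narrow primate
clade.  :func:`conservation_histogram` summarizes a catalog as the
distribution of per-intron conserved-species counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import AlignIO

from .annot_io import Catalog, CatalogError, intron_chain_of

__all__ = [
    "MafRow",
    "MafBlock",
    "MafError",
    "ConservationRecord",
    "read_maf",
    "AlignmentIndex",
    "intron_boundary_bases",
    "conservation_count",
    "conservation_histogram",
]

_RC = str.maketrans("ACGTacgt", "TGCAtgca")

#: Donor/acceptor dinucleotides counted as conserved.  The default is the
#: literal GT/AG consensus; minor canonical variants (GC-AG, AT-AC) can be
#: allowed by passing additional pairs.
CONSENSUS_PAIRS: frozenset[tuple[str, str]] = frozenset({("GT", "AG")})


class MafError(ValueError):
    """A MAF block violates the format invariants."""


@dataclass(frozen=True)
class MafRow:
    """One 's' line of a MAF block.

    ``start`` is 0-based on the source sequence's own strand, per the MAF
    standard; ``text`` is the aligned sequence including gap characters.
    """

    src: str          # e.g. "hg38.chr1"
    start: int
    size: int
    strand: str       # "+" | "-"
    src_size: int
    text: str

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def seqname(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) == 2 else parts[0]


@dataclass
class MafBlock:
    rows: tuple[MafRow, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise MafError("empty MAF block")
        width = len(self.rows[0].text)
        for row in self.rows:
            if len(row.text) != width:
                raise MafError("rows of unequal aligned length")
            ungapped = len(row.text) - row.text.count("-")
            if ungapped != row.size:
                raise MafError(
                    f"{row.src}: ungapped length {ungapped} != size {row.size}")

    def row_for_species(self, species: str) -> MafRow | None:
        """First row of ``species``; duplicate rows are logged and ignored."""
        found = None
        for row in self.rows:
            if row.species == species:
                if found is None:
                    found = row
                else:
                    warnings.warn(
                        f"duplicate rows for species {species}; first wins")
        return found

    def species(self) -> list[str]:
        seen: list[str] = []
        for row in self.rows:
            if row.species not in seen:
                seen.append(row.species)
        return seen


def read_maf(path: str | Path) -> Iterator[MafBlock]:
    """Stream the alignment blocks of a MAF file, validating each.

    Raises :class:`MafError` naming the (0-based) block index on a block
    whose rows disagree in aligned length or whose sizes are inconsistent.
    """
    with open(path) as fh:
        parser = AlignIO.parse(fh, "maf")
        index = 0
        while True:
            try:
                alignment = next(parser)
            except StopIteration:
                return
            except ValueError as err:
                raise MafError(f"{path}: block {index}: {err}") from err
            rows = []
            for rec in alignment:
                ann = rec.annotations
                strand = "+" if ann.get("strand", 1) == 1 else "-"
                rows.append(MafRow(
                    src=rec.id, start=int(ann["start"]),
                    size=int(ann["size"]), strand=strand,
                    src_size=int(ann.get("srcSize", 0)),
                    text=str(rec.seq)))
            try:
                yield MafBlock(tuple(rows))
            except MafError as err:
                raise MafError(f"{path}: block {index}: {err}") from err
            index += 1


class AlignmentIndex:
    """Random access from reference genome positions to alignment columns.

    Maps each 1-based forward-strand reference position covered by the
    alignment to its (block, column) and exposes the per-species character
    at that column.  Built once, queried per intron boundary.
    """

    def __init__(self, blocks: Iterable[MafBlock], ref_species: str):
        self.ref_species = ref_species
        self.blocks: list[MafBlock] = list(blocks)
        self._columns: dict[tuple[str, int], tuple[int, int]] = {}
        self._species: list[str] = []
        for bi, block in enumerate(self.blocks):
            for sp in block.species():
                if sp not in self._species:
                    self._species.append(sp)
            ref_row = block.row_for_species(ref_species)
            if ref_row is None:
                continue
            if ref_row.strand == "-":
                # forward-strand coordinate of the first aligned base
                pos = ref_row.src_size - ref_row.start
                step = -1
            else:
                pos = ref_row.start + 1
                step = 1
            for col, ch in enumerate(ref_row.text):
                if ch == "-":
                    continue
                key = (ref_row.seqname, pos)
                self._columns.setdefault(key, (bi, col))
                pos += step

    @property
    def species(self) -> list[str]:
        """All species seen in the alignment, reference included."""
        return list(self._species)

    @property
    def n_species(self) -> int:
        return len(self._species)

    def column_chars(self, chrom: str, pos: int) -> dict[str, str] | None:
        """Per-species uppercase character at reference position ``pos``.

        Returns None when the position is not covered by any block.  A
        species missing from the covering block, or gapped at the column,
        is absent from the returned mapping.
        """
        hit = self._columns.get((chrom, pos))
        if hit is None:
            return None
        block_index, col = hit
        block = self.blocks[block_index]
        chars: dict[str, str] = {}
        for sp in block.species():
            row = block.row_for_species(sp)
            ch = row.text[col]
            if ch != "-":
                chars[sp] = ch.upper()
        return chars


@dataclass
class ConservationRecord:
    """Per-intron conservation: boundary 2-mers per species and the count."""

    chrom: str
    donor_pos: int
    acceptor_pos: int
    strand: str
    covered: bool
    boundary_2mers: dict[str, tuple[str, str]] = field(default_factory=dict)
    n_species_conserved: int = 0


def intron_boundary_bases(intron: tuple[str, int, int, str],
                          index: AlignmentIndex
                          ) -> dict[str, tuple[str, str]] | None:
    """Per-species (donor 2-mer, acceptor 2-mer) in transcript orientation.

    ``intron`` is (chrom, donor_pos, acceptor_pos, strand) with positions
    the first and last intron base in forward genomic coordinates.  For
    minus-strand introns the 2-mers are reverse-complemented (and swapped)
    so the donor always reads 5'->3' on the transcript.  Species gapped or
    absent at any of the four boundary columns are omitted.  Returns None
    when any of the four reference positions is not covered by the
    alignment.
    """
    chrom, donor, acceptor, strand = intron
    positions = (donor, donor + 1, acceptor - 1, acceptor)
    per_pos = [index.column_chars(chrom, p) for p in positions]
    if any(chars is None for chars in per_pos):
        return None
    out: dict[str, tuple[str, str]] = {}
    for sp in index.species:
        chars = [cp.get(sp) for cp in per_pos]
        if any(c is None for c in chars):
            continue
        left = chars[0] + chars[1]    # forward 5' dinucleotide
        right = chars[2] + chars[3]   # forward 3' dinucleotide
        if strand == "+":
            out[sp] = (left, right)
        else:
            out[sp] = (right.translate(_RC)[::-1], left.translate(_RC)[::-1])
    return out


def conservation_count(intron: tuple[str, int, int, str],
                       index: AlignmentIndex,
                       consensus: frozenset[tuple[str, str]] = CONSENSUS_PAIRS
                       ) -> ConservationRecord:
    """Count species preserving the consensus dinucleotides at both ends.

    The reference species is counted like any other; an intron whose
    reference boundaries are themselves non-consensus simply does not get
    the reference's vote.  Uncovered introns are flagged and excluded from
    histograms.
    """
    chrom, donor, acceptor, strand = intron
    twomers = intron_boundary_bases(intron, index)
    if twomers is None:
        return ConservationRecord(chrom, donor, acceptor, strand,
                                  covered=False)
    n = sum(1 for pair in twomers.values() if pair in consensus)
    return ConservationRecord(chrom, donor, acceptor, strand, covered=True,
                              boundary_2mers=twomers, n_species_conserved=n)


def conservation_histogram(catalog: Catalog,
                           maf: str | Path | Iterable[MafBlock],
                           ref_species: str,
                           biotype: str | None = None,
                           consensus: frozenset[tuple[str, str]] = CONSENSUS_PAIRS
                           ) -> tuple[dict[int, int], list[ConservationRecord]]:
    """Histogram of conserved-species counts over a catalog's introns.

    Introns are deduplicated across transcripts (the same intron used by
    five isoforms is one observation).  ``biotype`` restricts to
    transcripts of that biotype.  Returns (histogram, per-intron records);
    the histogram covers covered introns only, and its bin counts sum to
    their number.
    """
    if isinstance(maf, (str, Path)):
        blocks = list(read_maf(maf))
    else:
        blocks = list(maf)
    index = AlignmentIndex(blocks, ref_species)

    introns: set[tuple[str, int, int, str]] = set()
    for t in catalog.transcripts():
        if biotype is not None and t.biotype != biotype:
            continue
        chain = intron_chain_of(t)
        for donor, acceptor in chain.introns:
            introns.add((chain.chrom, donor, acceptor, chain.strand))

    histogram: dict[int, int] = {}
    records: list[ConservationRecord] = []
    for intron in sorted(introns):
        record = conservation_count(intron, index, consensus)
        records.append(record)
        if record.covered:
            n = record.n_species_conserved
            histogram[n] = histogram.get(n, 0) + 1
    return histogram, records
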