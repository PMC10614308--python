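"""Transcript catalog I/O and the core data model.

This module defines the genomic data model shared by the whole toolkit
(:class:`GenomeInterval`, :class:`Transcript`, :class:`IntronChain`,
:class:`Catalog`, :class:`ProteinRecord`) and the operations that move
catalogs in and out of standard formats:

* :func:`read_gtf` parses GTF2.2 or GFF3 into a :class:`Catalog`;
* :func:`write_gtf` serializes a catalog back to GTF2.2 with CDS frames;
* :func:`intron_chain_of` derives the intron chain that serves as the
  transcript-equivalence key everywhere else in the package;
* :func:`translate_cds` produces the protein encoded by a transcript's
  CDS chain, flagging invalid open reading frames.

All interface coordinates are 1-based and inclusive on both ends (the GTF
convention).  Stored CDS chains are normalized to *include* the stop codon:
``stop_codon`` features found on input are merged into the CDS chain, and
translation always strips the trailing stop from the protein.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio.Seq import Seq
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

__all__ = [
    "GenomeInterval",
    "Transcript",
    "IntronChain",
    "Catalog",
    "ProteinRecord",
    "Genome",
    "CatalogError",
    "GtfParseError",
    "InvalidOrfError",
    "read_gtf",
    "write_gtf",
    "intron_chain_of",
    "translate_cds",
    "try_translate",
    "orf_flaws",
    "spliced_sequence",
    "read_support_tsv",
    "apply_support",
]


class CatalogError(ValueError):
    """A catalog or transcript violates a structural invariant."""


class GtfParseError(CatalogError):
    """A GTF/GFF3 file could not be parsed."""


class InvalidOrfError(ValueError):
    """A CDS chain does not encode a valid open reading frame.

    ``reason`` is one of ``cds_length_not_multiple_of_3``, ``internal_stop``
    or ``empty_cds``; the flag is consumed downstream by the filter cascade
    rather than treated as fatal in batch processing.
    """

    def __init__(self, transcript_id: str, reason: str):
        super().__init__(f"invalid ORF in {transcript_id}: {reason}")
        self.transcript_id = transcript_id
        self.reason = reason


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A closed genomic interval (1-based, inclusive) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CatalogError("interval chrom must be non-empty")
        if self.start > self.end:
            raise CatalogError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in ("+", "-"):
            raise CatalogError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap_len(self, other: "GenomeInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class IntronChain:
    """Ordered intron coordinates of a transcript; the matching key.

    Each intron is ``(donor_pos, acceptor_pos)``: the first and last base of
    the intron in forward genomic coordinates, 1-based inclusive.  Empty for
    single-exon transcripts.
    """

    chrom: str
    strand: str
    introns: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        for donor, acceptor in self.introns:
            if donor > acceptor:
                raise CatalogError(f"intron donor {donor} > acceptor {acceptor}")
            if donor <= prev_end:
                raise CatalogError("introns must be sorted and non-overlapping")
            prev_end = acceptor

    def __len__(self) -> int:
        return len(self.introns)

    def __bool__(self) -> bool:
        return bool(self.introns)


@dataclass
class Transcript:
    """One transcript: an exon chain, an optional CDS chain, and metadata.

    ``biotype`` is ``protein_coding``, ``lncRNA`` or ``other:<tag>``.
    ``n_samples`` and ``tpm_total`` carry expression support (number of
    samples the transcript was assembled in; cumulative TPM across samples)
    and default to zero, which every filter treats as "no support".
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomeInterval, ...]
    cds: tuple[GenomeInterval, ...] = ()
    biotype: str = "other:unknown"
    n_samples: int = 0
    tpm_total: float = 0.0
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        self.cds = tuple(sorted(self.cds, key=lambda c: c.start))
        self.check()

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def is_coding(self) -> bool:
        return self.biotype == "protein_coding"

    def cds_len(self) -> int:
        return sum(len(c) for c in self.cds)

    def check(self) -> None:
        """Enforce structural invariants; raise :class:`CatalogError`.

        Note: total CDS length modulo 3 is *not* enforced here — that flaw
        is surfaced by :func:`translate_cds` / :func:`orf_flaws` so that
        batch pipelines can drop (rather than crash on) invalid ORFs.
        """
        if not self.exons:
            raise CatalogError(f"{self.transcript_id}: transcript has no exons")
        chrom, strand = self.exons[0].chrom, self.exons[0].strand
        prev_end = 0
        for exon in self.exons:
            if exon.chrom != chrom or exon.strand != strand:
                raise CatalogError(
                    f"{self.transcript_id}: exons on mixed chrom/strand"
                )
            if exon.start <= prev_end:
                raise CatalogError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = exon.end
        prev_end = 0
        for seg in self.cds:
            if seg.start <= prev_end:
                raise CatalogError(f"{self.transcript_id}: CDS segments overlap")
            prev_end = seg.end
            if not any(e.contains(seg) for e in self.exons):
                raise CatalogError(
                    f"{self.transcript_id}: CDS segment "
                    f"{seg.chrom}:{seg.start}-{seg.end} not inside any exon"
                )

    def with_cds(self, cds: tuple[GenomeInterval, ...]) -> "Transcript":
        return replace(self, cds=cds)


@dataclass(frozen=True)
class ProteinRecord:
    """A translated protein: identifier, sequence without stop symbol."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CatalogError(f"{self.protein_id}: empty protein sequence")
        if "*" in self.sequence:
            raise CatalogError(f"{self.protein_id}: stop symbol in sequence")

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


class Catalog:
    """A named set of gene loci, each holding a list of transcripts.

    Transcripts are reachable from exactly one gene.  Derived indexes
    (intron-chain map, per-strand exon interval trees, genome-wide intron
    set) are computed on demand from the current gene map.
    """

    def __init__(self, name: str = "catalog",
                 transcripts: Iterable[Transcript] = ()):
        self.name = name
        self.genes: dict[str, list[Transcript]] = {}
        self._by_id: dict[str, Transcript] = {}
        for t in transcripts:
            self.add(t)

    def add(self, t: Transcript) -> None:
        if t.transcript_id in self._by_id:
            raise CatalogError(f"duplicate transcript_id {t.transcript_id}")
        self.genes.setdefault(t.gene_id, []).append(t)
        self._by_id[t.transcript_id] = t

    def __len__(self) -> int:
        return len(self._by_id)

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._by_id

    def __getitem__(self, transcript_id: str) -> Transcript:
        return self._by_id[transcript_id]

    def transcripts(self) -> Iterator[Transcript]:
        for gene in self.genes.values():
            yield from gene

    def transcript_ids(self) -> list[str]:
        return [t.transcript_id for t in self.transcripts()]

    def subset(self, keep_ids: Iterable[str], name: str | None = None) -> "Catalog":
        keep = set(keep_ids)
        return Catalog(name or self.name,
                       (t for t in self.transcripts() if t.transcript_id in keep))

    def copy(self, name: str | None = None) -> "Catalog":
        return Catalog(name or self.name, self.transcripts())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalog):
            return NotImplemented
        mine = {g: sorted(ts, key=lambda t: t.transcript_id)
                for g, ts in self.genes.items()}
        theirs = {g: sorted(ts, key=lambda t: t.transcript_id)
                  for g, ts in other.genes.items()}
        return mine == theirs

    # ---- derived indexes -------------------------------------------------

    def chain_index(self) -> dict[IntronChain, list[str]]:
        """Map intron chain -> sorted transcript IDs (multi-exon only)."""
        index: dict[IntronChain, list[str]] = {}
        for t in self.transcripts():
            chain = intron_chain_of(t)
            if chain:
                index.setdefault(chain, []).append(t.transcript_id)
        for tids in index.values():
            tids.sort()
        return index

    def intron_set(self) -> set[tuple[str, str, int, int]]:
        """All distinct introns as (chrom, strand, donor, acceptor)."""
        out: set[tuple[str, str, int, int]] = set()
        for t in self.transcripts():
            chain = intron_chain_of(t)
            for donor, acceptor in chain.introns:
                out.add((chain.chrom, chain.strand, donor, acceptor))
        return out

    def exon_trees(self) -> dict[tuple[str, str], IntervalTree]:
        """Per (chrom, strand) interval trees over exons, payload gene_id."""
        trees: dict[tuple[str, str], IntervalTree] = {}
        for t in self.transcripts():
            for exon in t.exons:
                tree = trees.setdefault((exon.chrom, exon.strand), IntervalTree())
                # IntervalTree is half-open; store [start, end+1)
                tree.addi(exon.start, exon.end + 1, t.gene_id)
        return trees


# ---------------------------------------------------------------------------
# Genome access


class Genome:
    """Uniform 1-based inclusive access to FASTA files or in-memory dicts."""

    def __init__(self, source: str | Path | Mapping[str, str]):
        if isinstance(source, (str, Path)):
            import pyfaidx

            self._fasta = pyfaidx.Fasta(str(source))
            self._dict = None
        else:
            self._fasta = None
            self._dict = {k: v.upper() for k, v in source.items()}

    def __contains__(self, chrom: str) -> bool:
        if self._dict is not None:
            return chrom in self._dict
        return chrom in self._fasta

    def chroms(self) -> list[str]:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fasta.keys())

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand sequence for [start, end], 1-based inclusive."""
        if start < 1 or end < start:
            raise ValueError(f"bad fetch range {chrom}:{start}-{end}")
        if self._dict is not None:
            return self._dict[chrom][start - 1 : end]
        return str(self._fasta[chrom][start - 1 : end]).upper()


def as_genome(genome: "Genome | str | Path | Mapping[str, str]") -> Genome:
    return genome if isinstance(genome, Genome) else Genome(genome)


# ---------------------------------------------------------------------------
# Derived features


def intron_chain_of(t: Transcript) -> IntronChain:
    """The ordered intron coordinates of ``t`` (empty for single-exon)."""
    introns = tuple(
        (t.exons[i].end + 1, t.exons[i + 1].start - 1)
        for i in range(len(t.exons) - 1)
    )
    return IntronChain(t.chrom, t.strand, introns)


def spliced_sequence(t: Transcript, genome, segments=None) -> str:
    """Spliced sequence of ``segments`` (default: exons), 5'->3' on t's strand."""
    g = as_genome(genome)
    segs = t.exons if segments is None else segments
    forward = "".join(g.fetch(s.chrom, s.start, s.end) for s in sorted(
        segs, key=lambda s: s.start))
    if t.strand == "-":
        return str(Seq(forward).reverse_complement())
    return forward


def translate_cds(t: Transcript, genome) -> ProteinRecord:
    """Translate the spliced CDS of ``t`` with the standard genetic code.

    The CDS is read 5'->3' on the transcript's strand (reverse-complemented
    for minus-strand transcripts).  A trailing stop codon, if present, is
    excluded from the returned protein.  Raises :class:`InvalidOrfError` on
    an internal stop codon or a CDS length that is not a multiple of 3.
    """
    if not t.cds:
        raise InvalidOrfError(t.transcript_id, "empty_cds")
    nt = spliced_sequence(t, genome, t.cds)
    if len(nt) % 3 != 0:
        raise InvalidOrfError(t.transcript_id, "cds_length_not_multiple_of_3")
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise InvalidOrfError(t.transcript_id, "internal_stop")
    if not aa:
        raise InvalidOrfError(t.transcript_id, "empty_cds")
    return ProteinRecord(t.transcript_id, aa)


def try_translate(t: Transcript, genome) -> tuple[ProteinRecord | None, str | None]:
    """Batch-friendly :func:`translate_cds`: (protein, None) or (None, reason)."""
    try:
        return translate_cds(t, genome), None
    except InvalidOrfError as err:
        return None, err.reason


def orf_flaws(t: Transcript, genome) -> list[str]:
    """All reasons the CDS of ``t`` fails to be a valid ATG..stop ORF.

    Beyond the translation-level flaws this also checks that the first
    codon is ATG and the last codon is a stop (the stored CDS chain
    includes the stop codon by convention).
    """
    if not t.cds:
        return ["no_cds"]
    flaws: list[str] = []
    nt = spliced_sequence(t, genome, t.cds)
    if len(nt) % 3 != 0:
        return ["cds_length_not_multiple_of_3"]
    if not nt.startswith("ATG"):
        flaws.append("no_start_codon")
    if nt[-3:] not in ("TAA", "TAG", "TGA"):
        flaws.append("no_stop_codon")
    aa = str(Seq(nt).translate())
    body = aa[:-1] if aa.endswith("*") else aa
    if "*" in body:
        flaws.append("internal_stop")
    return flaws


# ---------------------------------------------------------------------------
# GTF / GFF3 reading


_BIOTYPE_KEYS = ("gene_type", "gene_biotype", "transcript_biotype")
_TRANSCRIPT_TYPES = {"transcript", "mRNA", "lnc_RNA", "ncRNA"}


def _normalize_biotype(raw: str | None) -> str:
    if raw is None:
        return "other:unknown"
    if raw == "protein_coding":
        return "protein_coding"
    if raw in ("lncRNA", "lincRNA", "lnc_RNA"):
        return "lncRNA"
    return f"other:{raw}"


def _raw_biotype(biotype: str) -> str:
    return biotype.split(":", 1)[1] if biotype.startswith("other:") else biotype


def _first_attr(attrs, *keys) -> str | None:
    for key in keys:
        if key in attrs and attrs[key]:
            return attrs[key][0]
    return None


def _merge_bookended(segments: list[GenomeInterval]) -> tuple[GenomeInterval, ...]:
    """Sort segments and fuse ones that abut (end + 1 == next start)."""
    merged: list[GenomeInterval] = []
    for seg in sorted(segments, key=lambda s: s.start):
        if merged and seg.start == merged[-1].end + 1:
            prev = merged.pop()
            seg = GenomeInterval(prev.chrom, prev.start, seg.end, prev.strand)
        merged.append(seg)
    return tuple(merged)


def read_gtf(path: str | Path, genome: str | Path | None = None,
             name: str | None = None) -> Catalog:
    """Parse a GTF2.2 or GFF3 file into a :class:`Catalog`.

    Exons are grouped under transcripts via the ``transcript_id`` attribute
    (GTF) or ``Parent`` (GFF3).  ``stop_codon`` features are merged into the
    CDS chain so stored CDS chains always include the stop codon.  Biotypes
    are read from ``gene_type`` / ``gene_biotype`` / ``transcript_biotype``
    in that priority order; unknown values are preserved as ``other:<tag>``.
    ``genome`` is accepted for interface symmetry (sequence is not needed to
    build the catalog) and is unused here.
    """
    path = Path(path)
    # accumulate per transcript id
    meta: dict[str, dict] = {}
    order: list[str] = []

    def rec(tid: str) -> dict:
        if tid not in meta:
            meta[tid] = {"gene_id": None, "biotype_raw": None, "exons": [],
                         "cds": [], "stop": [], "n_samples": 0,
                         "tpm_total": 0.0, "tags": frozenset()}
            order.append(tid)
        return meta[tid]

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise GtfParseError(
                    f"{path}:{lineno}: non-numeric coordinates "
                    f"{fields[3]!r}/{fields[4]!r}"
                ) from None
            try:
                feat = feature_from_line(line)
            except Exception as err:  # pragma: no cover - gffutils is lenient
                raise GtfParseError(f"{path}:{lineno}: {err}") from err
            ftype = feat.featuretype
            attrs = feat.attributes
            if ftype in _TRANSCRIPT_TYPES:
                tid = _first_attr(attrs, "transcript_id", "ID")
                if tid is None:
                    raise GtfParseError(
                        f"{path}:{lineno}: transcript feature without "
                        "transcript_id/ID"
                    )
                r = rec(tid)
                r["gene_id"] = (_first_attr(attrs, "gene_id", "Parent")
                                or r["gene_id"])
                r["biotype_raw"] = (_first_attr(attrs, *_BIOTYPE_KEYS)
                                    or r["biotype_raw"])
                ns = _first_attr(attrs, "n_samples")
                if ns is not None:
                    r["n_samples"] = int(ns)
                tpm = _first_attr(attrs, "tpm_total")
                if tpm is not None:
                    r["tpm_total"] = float(tpm)
                tags = _first_attr(attrs, "tags")
                if tags:
                    r["tags"] = frozenset(tags.split(","))
            elif ftype in ("exon", "CDS", "stop_codon"):
                tid = _first_attr(attrs, "transcript_id", "Parent")
                if tid is None:
                    raise GtfParseError(
                        f"{path}:{lineno}: {ftype} feature without "
                        "transcript_id/Parent"
                    )
                r = rec(tid)
                if r["gene_id"] is None:
                    r["gene_id"] = _first_attr(attrs, "gene_id")
                if r["biotype_raw"] is None:
                    r["biotype_raw"] = _first_attr(attrs, *_BIOTYPE_KEYS)
                iv = GenomeInterval(feat.seqid, feat.start, feat.end, feat.strand)
                key = {"exon": "exons", "CDS": "cds", "stop_codon": "stop"}[ftype]
                r[key].append(iv)
            # other feature types (gene, five_prime_utr, ...) are ignored

    catalog = Catalog(name or path.stem)
    for tid in order:
        r = meta[tid]
        if not r["exons"]:
            # transcript line without exons: skip silently (header-only files)
            continue
        gene_id = r["gene_id"] or tid
        cds = _merge_bookended(r["cds"] + r["stop"])
        try:
            t = Transcript(
                transcript_id=tid,
                gene_id=gene_id,
                exons=tuple(r["exons"]),
                cds=cds,
                biotype=_normalize_biotype(r["biotype_raw"]),
                n_samples=r["n_samples"],
                tpm_total=r["tpm_total"],
                tags=r["tags"],
            )
        except CatalogError as err:
            raise GtfParseError(f"{path}: transcript {tid}: {err}") from err
        catalog.add(t)
    return catalog


# ---------------------------------------------------------------------------
# GTF writing


def _cds_frames(t: Transcript) -> dict[GenomeInterval, int]:
    """GTF frame for each CDS segment, walking the chain 5'->3'."""
    segs = list(t.cds) if t.strand == "+" else list(reversed(t.cds))
    frames: dict[GenomeInterval, int] = {}
    cumulative = 0
    for seg in segs:
        frames[seg] = (3 - cumulative % 3) % 3
        cumulative += len(seg)
    return frames


def _fmt_float(x: float) -> str:
    return repr(float(x))


def write_gtf(catalog: Catalog, path: str | Path,
              header: Iterable[str] = ()) -> None:
    """Write ``catalog`` as GTF2.2; round-trips through :func:`read_gtf`.

    Support metadata (``n_samples``, ``tpm_total``, ``tags``) is carried as
    transcript attributes so the parse-write-parse round trip is the
    identity on the data model.
    """
    lines: list[str] = [f"# {h}" for h in header]
    for gene_id in catalog.genes:
        for t in catalog.genes[gene_id]:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_type "{_raw_biotype(t.biotype)}"; '
                f'n_samples "{t.n_samples}"; '
                f'tpm_total "{_fmt_float(t.tpm_total)}";'
            )
            if t.tags:
                attrs += f' tags "{",".join(sorted(t.tags))}";'
            row = [t.chrom, "txcurate", "transcript", str(t.start), str(t.end),
                   ".", t.strand, ".", attrs]
            lines.append("\t".join(row))
            for exon in t.exons:
                lines.append("\t".join([
                    t.chrom, "txcurate", "exon", str(exon.start), str(exon.end),
                    ".", t.strand, ".",
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";',
                ]))
            frames = _cds_frames(t)
            for seg in t.cds:
                lines.append("\t".join([
                    t.chrom, "txcurate", "CDS", str(seg.start), str(seg.end),
                    ".", t.strand, str(frames[seg]),
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";',
                ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Support table


def read_support_tsv(path: str | Path) -> dict[str, tuple[float, int]]:
    """Read the 3-column support TSV: transcript_id, tpm_total, n_samples.

    A header row is required.  Returns transcript_id -> (tpm_total,
    n_samples).
    """
    table: dict[str, tuple[float, int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 3:
            raise CatalogError(f"{path}: support TSV needs 3 columns")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise CatalogError(f"{path}:{lineno}: expected 3 columns")
            table[parts[0]] = (float(parts[1]), int(parts[2]))
    return table


def apply_support(catalog: Catalog,
                  table: Mapping[str, tuple[float, int]]) -> Catalog:
    """Return a copy of ``catalog`` with support fields filled from ``table``.

    Transcripts missing from the table keep (0.0, 0): no support.
    """
    out = Catalog(catalog.name)
    for t in catalog.transcripts():
        tpm, ns = table.get(t.transcript_id, (0.0, 0))
        out.add(replace(t, tpm_total=tpm, n_samples=ns))
    return out
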