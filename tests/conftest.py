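"""Shared fixtures: synthetic bundles and small hand-built catalogs."""

from __future__ import annotations

import pytest
from hypothesis import settings

from txcurate.annot_io import Catalog, GenomeInterval, Transcript
from txcurate.filter_cascade import run_full_cascade
from txcurate.fixtures import FixtureSpec, make_bundle

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_bundle():
    """The standard 200-transcript bundle with all defect classes planted."""
    return make_bundle(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def default_cascade(default_bundle):
    b = default_bundle
    return run_full_cascade(b.candidates, genome=b.genome, ref=b.ref,
                            beta=b.beta, scores=b.scores)


def single_exon_tx(tid: str, gid: str, start: int = 100, length: int = 300,
                   chrom: str = "chr1", strand: str = "+",
                   biotype: str = "protein_coding", **kw) -> Transcript:
    exon = GenomeInterval(chrom, start, start + length - 1, strand)
    return Transcript(tid, gid, exons=(exon,), biotype=biotype, **kw)


def exons(*spans: tuple[int, int], chrom: str = "chr1",
          strand: str = "+") -> tuple[GenomeInterval, ...]:
    return tuple(GenomeInterval(chrom, s, e, strand) for s, e in spans)


@pytest.fixture
def toy_catalog() -> Catalog:
    t = Transcript("T1", "G1", exons=exons((100, 200), (300, 400), (500, 600)),
                   biotype="protein_coding")
    return Catalog("toy", [t])
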