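"""Every cascade stage, plus composition, audit and oracle properties."""

from __future__ import annotations

from collections import Counter

import pytest

from txcurate.annot_io import Catalog, ProteinRecord, Transcript, intron_chain_of
from txcurate.filter_cascade import (
    CascadeConfig,
    STAGES,
    StructureScoreTable,
    containment_resolution,
    dedup_identical,
    fragment_filter,
    intron_support_filter,
    orf_validity_filter,
    readthrough_filter,
    run_full_cascade,
    structure_gate,
    substring_filter,
    translate_catalog,
    truncation_filter,
    truncation_keep,
)
from txcurate.fixtures import (
    FixtureSpec,
    TTN_SHORT_FUNCTIONAL_ISOFORM,
    make_bundle,
    ttn_isoform_lengths,
)

from conftest import exons, single_exon_tx


EXPECTED_STAGE = {
    "invalid_orf": "orf_validity",
    "unsupported_intron": "intron_support",
    "truncated": "truncation",
    "low_plddt": "structure_gate",
    "substring": "substring",
    "duplicate_protein": "dedup",
    "readthrough": "readthrough",
}


def proteins_of(*pairs: tuple[str, str]) -> dict[str, ProteinRecord]:
    return {tid: ProteinRecord(tid, seq) for tid, seq in pairs}


class TestTruncationRule:
    def test_titin_lengths_threshold_arithmetic(self):
        """One-fifth of the 35,991aa maximum keeps exactly 6 isoforms."""
        kept = truncation_keep(ttn_isoform_lengths())
        assert len(kept) == 6
        lengths = ttn_isoform_lengths()
        assert sorted(lengths[t] for t in kept) == [
            26926, 27051, 27118, 33423, 34350, 35991]

    def test_whitelisting_the_short_functional_isoform_keeps_seven(self):
        kept = truncation_keep(ttn_isoform_lengths(),
                               {TTN_SHORT_FUNCTIONAL_ISOFORM})
        assert len(kept) == 7
        assert TTN_SHORT_FUNCTIONAL_ISOFORM in kept

    def test_equal_lengths_all_kept(self):
        assert truncation_keep({"a": 100, "b": 100}) == {"a", "b"}

    def test_catalog_filter_spares_single_isoform_loci(self):
        catalog = Catalog("c", [
            single_exon_tx("t1", "g1", 100), single_exon_tx("t2", "g1", 1000),
            single_exon_tx("t3", "g2", 5000)])
        proteins = proteins_of(("t1", "M" + "A" * 9), ("t2", "M" + "A" * 99),
                               ("t3", "MA"))
        out, decisions = truncation_filter(catalog, proteins)
        assert out.transcript_ids() == ["t2", "t3"]  # g2 untouched
        dropped = {d.transcript_id for d in decisions if d.action == "drop"}
        assert dropped == {"t1"}


class TestStructureGate:
    def test_inclusive_boundary_at_70(self):
        catalog = Catalog("c", [single_exon_tx("hi", "g", 100),
                                single_exon_tx("lo", "g", 1000),
                                single_exon_tx("unscored", "g", 2000)])
        scores = StructureScoreTable({"hi": 70.0, "lo": 69.9})
        out, decisions = structure_gate(catalog, scores, threshold=70.0)
        assert out.transcript_ids() == ["hi"]
        reasons = {d.transcript_id: d.reason for d in decisions}
        assert reasons["unscored"] == "unscored"


class TestSubstringFilter:
    @pytest.mark.parametrize("candidate,verdict", [
        ("MKL", "drop"),    # contiguous substring of AMKLV
        ("AMKLV", "drop"),  # equality is a substring
        ("MLK", "keep"),    # not contiguous
    ])
    def test_substring_semantics(self, candidate, verdict):
        catalog = Catalog("c", [single_exon_tx("t", "g")])
        proteins = proteins_of(("t", candidate))
        beta = [ProteinRecord("b", "AMKLV")]
        _, decisions = substring_filter(catalog, proteins, beta)
        assert decisions[0].action == verdict


class TestContainmentResolution:
    def _setup(self, candidate_scores: dict[str, float], beta_score=76.0):
        beta = Catalog("beta", [single_exon_tx("b1", "g", 5000)])
        beta_proteins = proteins_of(("b1", "MKLV"))
        candidates = Catalog("c", [
            single_exon_tx(tid, "g", 100 + i * 1000)
            for i, tid in enumerate(candidate_scores)])
        proteins = {tid: ProteinRecord(tid, f"A{'X' * i}MKLVZ")
                    for i, tid in enumerate(candidate_scores)}
        scores = StructureScoreTable({**candidate_scores, "b1": beta_score})
        return candidates, proteins, beta, beta_proteins, scores

    def test_locus_best_containing_candidate_kept(self):
        args = self._setup({"c1": 80.0}, beta_score=76.0)
        out, _ = containment_resolution(*args)
        assert out.transcript_ids() == ["c1"]

    def test_beaten_by_beta_isoform_dropped(self):
        args = self._setup({"c1": 75.0}, beta_score=82.0)
        out, _ = containment_resolution(*args)
        assert out.transcript_ids() == []

    def test_two_containing_candidates_only_maximum_survives(self):
        args = self._setup({"c1": 78.0, "c2": 80.0}, beta_score=70.0)
        out, _ = containment_resolution(*args)
        assert out.transcript_ids() == ["c2"]


class TestFragmentFilter:
    @pytest.mark.parametrize("aa,longest,verdict", [
        (69, 69, "drop"),     # rule (a): < 70aa
        (190, 300, "drop"),   # rule (b): 190 < 200
        (200, 300, "keep"),   # inclusive boundary: 200 >= 200
    ])
    def test_length_rules(self, aa, longest, verdict):
        catalog = Catalog("c", [single_exon_tx("t", "g", 100),
                                single_exon_tx("big", "g", 5000)])
        proteins = proteins_of(("t", "M" + "A" * (aa - 1)),
                               ("big", "M" + "A" * (longest - 1)))
        _, decisions = fragment_filter(catalog, proteins)
        verdicts = {d.transcript_id: d.action for d in decisions}
        assert verdicts["t"] == verdict


class TestDedup:
    def _catalog(self, n_samples: dict[str, int], chains=None):
        txs = []
        for i, (tid, ns) in enumerate(n_samples.items()):
            if chains and tid in chains:
                txs.append(Transcript(tid, "g", exons=chains[tid],
                                      biotype="protein_coding",
                                      n_samples=ns))
            else:
                txs.append(single_exon_tx(tid, "g", 100 + i * 1000,
                                          n_samples=ns))
        return Catalog("c", txs)

    def test_reference_chain_match_outranks_sample_count(self):
        chain = exons((100, 200), (300, 400))
        catalog = self._catalog({"match": 1, "deep": 99, "other": 50},
                                chains={"match": chain})
        proteins = proteins_of(*((t, "MSAME") for t in
                                 ("match", "deep", "other")))
        ref = Catalog("ref", [Transcript("r", "rg", exons=chain,
                                         biotype="protein_coding")])
        out, _ = dedup_identical(catalog, proteins, [ref])
        assert out.transcript_ids() == ["match"]

    def test_most_samples_wins_without_reference(self):
        catalog = self._catalog({"a": 12, "b": 40})
        proteins = proteins_of(("a", "MSAME"), ("b", "MSAME"))
        out, _ = dedup_identical(catalog, proteins, [])
        assert out.transcript_ids() == ["b"]

    def test_equal_samples_resolved_lexicographically(self):
        catalog = self._catalog({"zz": 7, "aa": 7})
        proteins = proteins_of(("zz", "MSAME"), ("aa", "MSAME"))
        out, _ = dedup_identical(catalog, proteins, [])
        assert out.transcript_ids() == ["aa"]

    def test_decision_log_byte_identical_across_runs(self, default_bundle):
        b = default_bundle
        proteins, _ = translate_catalog(b.candidates, b.genome)
        logs = []
        for _ in range(2):
            _, decisions = dedup_identical(b.candidates, proteins, [b.ref])
            logs.append("\n".join(map(repr, decisions)))
        assert logs[0] == logs[1]


class TestReadthrough:
    def _beta(self):
        return Catalog("beta", [
            Transcript("a1", "A", exons=exons((100, 200), (900, 1000)),
                       biotype="protein_coding"),
            single_exon_tx("b1", "B", 2000, 300),
            single_exon_tx("c1", "C", 5000, 300, strand="-")])

    def test_spanning_two_loci_dropped(self):
        cand = Catalog("c", [Transcript(
            "rt", "A", exons=exons((150, 250), (2000, 2100)),
            biotype="protein_coding")])
        out, _ = readthrough_filter(cand, self._beta())
        assert out.transcript_ids() == []

    def test_intronic_overlap_does_not_count(self):
        # exon at 300-800 sits inside A's intron; only exonic overlap counts
        cand = Catalog("c", [Transcript(
            "t", "A", exons=exons((150, 180), (300, 800)),
            biotype="protein_coding")])
        out, _ = readthrough_filter(cand, self._beta())
        assert out.transcript_ids() == ["t"]

    def test_opposite_strand_overlap_does_not_count(self):
        cand = Catalog("c", [Transcript(
            "t", "A", exons=exons((150, 250), (5000, 5100)),
            biotype="protein_coding")])
        out, _ = readthrough_filter(cand, self._beta())
        assert out.transcript_ids() == ["t"]


class TestBetaStagesOnFixtures:
    def test_orf_validity_recovers_planted_count(self):
        spec = FixtureSpec(seed=11, n_genes=20, n_transcripts=100,
                           planted_defects={"invalid_orf": 7})
        b = make_bundle(spec)
        out, decisions = orf_validity_filter(b.candidates, b.genome)
        assert len(out) == 93
        dropped = {d.transcript_id for d in decisions if d.action == "drop"}
        assert dropped == {t for t, c in b.truth.items()
                           if c == "invalid_orf"}

    def test_intron_support_recovers_planted_count(self):
        spec = FixtureSpec(seed=12, n_genes=7, n_transcripts=20,
                           planted_defects={"unsupported_intron": 6})
        b = make_bundle(spec)
        out, _ = intron_support_filter(b.candidates, b.ref, min_samples=3,
                                       genome=b.genome)
        assert len(out) == 14

    def test_reference_matched_introns_kept_without_support(self):
        spec = FixtureSpec(seed=13, n_genes=4, n_transcripts=8,
                           planted_defects={})
        b = make_bundle(spec)
        zero_support = Catalog("c")
        from dataclasses import replace
        for t in b.candidates.transcripts():
            zero_support.add(replace(t, n_samples=0))
        out, _ = intron_support_filter(zero_support, b.ref, min_samples=3,
                                       genome=b.genome)
        assert len(out) == len(b.candidates)

    def test_novel_noncanonical_intron_dropped_despite_support(self):
        spec = FixtureSpec(seed=14, n_genes=3, n_transcripts=6,
                           planted_defects={})
        b = make_bundle(spec)
        # sabotage one donor site in the genome: boundary becomes non-GT
        t = next(iter(b.candidates.transcripts()))
        donor, _ = intron_chain_of(t).introns[0]
        seq = list(b.genome[t.chrom])
        seq[donor - 1] = "A" if seq[donor - 1] != "A" else "C"
        genome = {t.chrom: "".join(seq)}
        empty_ref = Catalog("empty")
        out, decisions = intron_support_filter(b.candidates, empty_ref,
                                               min_samples=1, genome=genome)
        verdicts = {d.transcript_id: d.reason for d in decisions}
        assert verdicts[t.transcript_id] == "noncanonical_novel_intron"
        assert t.transcript_id not in out


class TestCascadeComposition:
    def test_planted_defects_removed_at_their_stage(self, default_bundle,
                                                    default_cascade):
        truth = default_bundle.truth
        stage_of = {d.transcript_id: d.stage
                    for d in default_cascade.decisions if d.action == "drop"}
        for tid, cls in truth.items():
            if cls == "clean":
                assert tid in default_cascade.survivors
            else:
                assert stage_of[tid] == EXPECTED_STAGE[cls], (tid, cls)

    def test_stage_report_is_monotone_and_contiguous(self, default_cascade):
        rows = default_cascade.report.rows
        assert [r[0] for r in rows] == list(STAGES)
        for (_, n_in, n_out), (_, next_in, _) in zip(rows, rows[1:]):
            assert n_out <= n_in
            assert next_in == n_out

    def test_disabling_any_stage_yields_a_superset(self, default_bundle,
                                                   default_cascade):
        b = default_bundle
        full = set(default_cascade.survivors.transcript_ids())
        for stage in STAGES:
            relaxed = run_full_cascade(
                b.candidates, genome=b.genome, ref=b.ref, beta=b.beta,
                scores=b.scores, disabled={stage})
            assert full <= set(relaxed.survivors.transcript_ids()), stage

    def test_identical_inputs_give_identical_decision_logs(self,
                                                           default_bundle):
        b = default_bundle
        logs = []
        for _ in range(2):
            result = run_full_cascade(b.candidates, genome=b.genome,
                                      ref=b.ref, beta=b.beta, scores=b.scores)
            logs.append(result.decisions_tsv())
        assert logs[0] == logs[1]

    def test_candidates_identical_to_beta_die_at_substring(self):
        spec = FixtureSpec(seed=15, n_genes=3, n_transcripts=6,
                           planted_defects={})
        b = make_bundle(spec)
        result = run_full_cascade(b.beta.copy("candidates"), genome=b.genome,
                                  ref=b.ref, beta=b.beta, scores=b.scores,
                                  disabled={"intron_support"})
        assert len(result.survivors) == 0
        substring_drops = [d for d in result.decisions
                           if d.stage == "substring" and d.action == "drop"]
        assert len(substring_drops) == len(b.beta)

    def test_empty_candidate_set_reports_zeros(self, default_bundle):
        b = default_bundle
        result = run_full_cascade(Catalog("none"), genome=b.genome,
                                  ref=b.ref, beta=b.beta, scores=b.scores)
        assert len(result.survivors) == 0
        assert all(r[1] == 0 and r[2] == 0 for r in result.report.rows)


class TestBruteForceOracle:
    """Survivors equal an independent, index-free re-derivation."""

    @staticmethod
    def brute_force(bundle, config: CascadeConfig):
        b = bundle
        from txcurate.annot_io import orf_flaws, try_translate

        proteins = {}
        for t in b.candidates.transcripts():
            p, _ = try_translate(t, b.genome)
            if p is not None:
                proteins[t.transcript_id] = p
        beta_proteins = {}
        for t in b.beta.transcripts():
            p, _ = try_translate(t, b.genome)
            if p is not None:
                beta_proteins[t.transcript_id] = p
        alive = [t for t in b.candidates.transcripts()]

        # 1. orf validity
        alive = [t for t in alive if not orf_flaws(t, b.genome)]
        # 2. intron support
        ref_introns = set()
        for t in b.ref.transcripts():
            ch = intron_chain_of(t)
            for d, a in ch.introns:
                ref_introns.add((ch.chrom, ch.strand, d, a))

        def intron_ok(t):
            ch = intron_chain_of(t)
            for d, a in ch.introns:
                if (ch.chrom, ch.strand, d, a) in ref_introns:
                    continue
                seq = b.genome[ch.chrom]
                five, three = seq[d - 1:d + 1], seq[a - 2:a]
                if ch.strand == "-":
                    comp = str.maketrans("ACGT", "TGCA")
                    five, three = (three.translate(comp)[::-1],
                                   five.translate(comp)[::-1])
                if (five, three) != ("GT", "AG"):
                    return False
                if t.n_samples < config.min_samples:
                    return False
            return True

        alive = [t for t in alive if intron_ok(t)]
        # 3. truncation
        out = []
        for t in alive:
            peers = [u for u in alive if u.gene_id == t.gene_id
                     and u.transcript_id in proteins]
            if t.transcript_id not in proteins or len(peers) <= 1:
                out.append(t)
                continue
            top = max(proteins[u.transcript_id].length_aa for u in peers)
            if proteins[t.transcript_id].length_aa >= \
                    config.truncation_fraction * top:
                out.append(t)
        alive = out
        # 4. structure gate
        alive = [t for t in alive
                 if b.scores.get(t.transcript_id) is not None
                 and b.scores.get(t.transcript_id) >= config.plddt_threshold]
        # 5. substring
        alive = [t for t in alive
                 if not any(proteins[t.transcript_id].sequence in bp.sequence
                            for bp in beta_proteins.values())]
        # 6. containment
        out = []
        for t in alive:
            mine = proteins[t.transcript_id].sequence
            beta_here = [bid for bid, bt in
                         ((x.transcript_id, x) for x in b.beta.transcripts())
                         if bt.gene_id == t.gene_id and bid in beta_proteins]
            contains = any(beta_proteins[bid].sequence != mine
                           and beta_proteins[bid].sequence in mine
                           for bid in beta_here)
            if not contains:
                out.append(t)
                continue
            pool = [b.scores.get(u.transcript_id) for u in alive
                    if u.gene_id == t.gene_id] + \
                   [b.scores.get(bid) for bid in beta_here]
            pool = [s for s in pool if s is not None]
            if b.scores.get(t.transcript_id) >= max(pool):
                out.append(t)
        alive = out
        # 7. fragment
        out = []
        for t in alive:
            aa = proteins[t.transcript_id].length_aa
            peers = [proteins[u.transcript_id].length_aa for u in alive
                     if u.gene_id == t.gene_id]
            peers += [bp.length_aa for x in b.beta.transcripts()
                      if x.gene_id == t.gene_id
                      for bp in [beta_proteins.get(x.transcript_id)] if bp]
            if aa >= config.min_protein_aa and \
                    aa >= config.fragment_fraction * max(peers):
                out.append(t)
        alive = out
        # 8. dedup
        ref_chains = {intron_chain_of(t) for t in b.ref.transcripts()
                      if intron_chain_of(t)}
        out = []
        for t in alive:
            group = [u for u in alive if u.gene_id == t.gene_id and
                     proteins[u.transcript_id].sequence ==
                     proteins[t.transcript_id].sequence]

            def rank(u):
                ch = intron_chain_of(u)
                return (not (bool(ch) and ch in ref_chains), -u.n_samples,
                        u.transcript_id)

            if min(group, key=rank) is t:
                out.append(t)
        alive = out
        # 9. readthrough
        out = []
        for t in alive:
            genes = set()
            for bt in b.beta.transcripts():
                if bt.strand != t.strand or bt.chrom != t.chrom:
                    continue
                for e in t.exons:
                    for be in bt.exons:
                        if e.start <= be.end and be.start <= e.end:
                            genes.add(bt.gene_id)
            if len(genes) < 2:
                out.append(t)
        return {t.transcript_id for t in out}

    def test_survivors_match_brute_force(self, default_bundle,
                                         default_cascade):
        expected = self.brute_force(default_bundle, CascadeConfig())
        assert set(default_cascade.survivors.transcript_ids()) == expected
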