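"""Motif matching, kinase sets, t-ranking, classic ES and permutation KSEA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from phosphoscreen.errors import ValidationError
from phosphoscreen.io import IntensityMatrix, SampleAnnotation
from phosphoscreen.ksea import (MotifPattern, build_kinase_sets,
                                enrichment_score_classic, ksea_run,
                                match_motifs, parse_motif_pattern,
                                rank_by_tstat)
from phosphoscreen.simulate import PhosphoSimConfig, simulate_phospho_dataset

import oracles
from conftest import make_record


class TestMotifs:
    def test_parse_basophilic_pattern(self):
        pat = parse_motif_pattern("PKA", "R-X-X-pS/pT")
        assert dict(pat.constraints) == {-3: frozenset("R"), 0: frozenset("ST")}

    def test_parse_bracket_groups(self):
        pat = parse_motif_pattern("K", "[RK]-X-pS-X-[DE]")
        assert dict(pat.constraints) == {
            -2: frozenset("RK"), 0: frozenset("S"), 2: frozenset("DE")}

    def test_match_requires_every_constraint(self):
        pat = parse_motif_pattern("PKA", "R-X-X-pS/pT")
        hit = "AAAAR" + "AA" + "S" + "AAAAAAA"  # R at -3 from centred S
        miss = "AAAAG" + "AA" + "S" + "AAAAAAA"
        assert match_motifs(hit, "S", [pat]) == {"PKA"}
        assert match_motifs(miss, "S", [pat]) == set()

    def test_padding_never_matches(self):
        pat = parse_motif_pattern("PKA", "R-X-X-pS")
        window = "____R" + "AA" + "S" + "AAAAAAA"
        assert match_motifs(window, "S", [pat]) == {"PKA"}
        padded = "_______S_______"
        assert match_motifs(padded, "S", [pat]) == set()

    def test_empty_pattern_list(self):
        assert match_motifs("AAAAAAASAAAAAAA", "S", []) == set()

    def test_malformed_window_rejected(self):
        with pytest.raises(ValidationError):
            match_motifs("SHORT", "S", [])

    def test_centre_constraint_must_be_phosphoacceptor(self):
        with pytest.raises(ValidationError):
            MotifPattern("bad", ((0, frozenset("A")),))


class TestKinaseSetSizeLimits:
    @pytest.mark.parametrize("n_matching,kept", [(5, False), (6, True)])
    def test_lower_bound_strictly_greater_than_five(self, n_matching, kept):
        pat = parse_motif_pattern("K1", "R-X-X-pS")
        win_hit = "AAAAR" + "AA" + "S" + "AAAAAAA"
        win_miss = "AAAAG" + "AA" + "S" + "AAAAAAA"
        peptides = [make_record(f"p{i}", win_hit) for i in range(n_matching)]
        peptides += [make_record("q0", win_miss)]
        m = IntensityMatrix.from_records(
            peptides, ["s1"], np.ones((len(peptides), 1)))
        sets = build_kinase_sets(m, [pat])
        assert bool(sets) is kept
        if kept:
            assert sets[0].size == n_matching

    def test_upper_bound_strictly_below_thousand(self):
        pat = parse_motif_pattern("K1", "R-X-X-pS")
        win_hit = "AAAAR" + "AA" + "S" + "AAAAAAA"
        peptides = [make_record(f"p{i}", win_hit) for i in range(1000)]
        m = IntensityMatrix.from_records(peptides, ["s1"], np.ones((1000, 1)))
        assert build_kinase_sets(m, [pat]) == []


class TestRanking:
    def _matrix(self, rows):
        peptides = [make_record(f"p{i}") for i in range(len(rows))]
        return IntensityMatrix.from_records(
            peptides, [f"s{j}" for j in range(len(rows[0]))], np.array(rows))

    def _anns(self, n_resp, n_non):
        return ([SampleAnnotation(f"s{i}", "standard", "responder")
                 for i in range(n_resp)]
                + [SampleAnnotation(f"s{i + n_resp}", "standard", "nonresponder")
                   for i in range(n_non)])

    def test_pooled_t_worked_case(self):
        """log2 groups [3,4,5] vs [0,1,2]: pooled t = 3/sqrt(2/3) ~ 3.674."""
        rows = [np.exp2([3, 4, 5, 0, 1, 2]) - 1]
        ranked = rank_by_tstat(self._matrix(rows), self._anns(3, 3))
        expected = oracles.pooled_t([3, 4, 5], [0, 1, 2])
        assert ranked["t"][0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(3 / np.sqrt(2 / 3))

    def test_agrees_with_scipy_ttest(self):
        rng = np.random.default_rng(3)
        rows = rng.lognormal(10, 1, size=(20, 9))
        ranked = rank_by_tstat(self._matrix(rows), self._anns(4, 5))
        log2 = np.log2(rows + 1)
        for _, r in ranked.iterrows():
            i = int(r["peptide_id"][1:])
            t_ref = stats.ttest_ind(log2[i, :4], log2[i, 4:], equal_var=True).statistic
            assert r["t"] == pytest.approx(t_ref, rel=1e-9)

    def test_zero_variance_gives_t_zero_and_lexicographic_ties(self):
        rows = [[4.0] * 6, [4.0] * 6]
        ranked = rank_by_tstat(self._matrix(rows), self._anns(3, 3))
        assert list(ranked["t"]) == [0.0, 0.0]
        assert list(ranked["peptide_id"]) == ["p0", "p1"]


class TestEnrichmentScore:
    def test_set_at_head_gives_plus_one(self):
        assert enrichment_score_classic(list("abcd"), {"a", "b"}) == 1.0

    def test_set_at_tail_gives_minus_one(self):
        assert enrichment_score_classic(list("abcd"), {"d"}) == -1.0

    def test_worked_running_sum(self):
        """N=5, member at rank 2: running sum [-.25, .75, .5, .25, 0]."""
        assert enrichment_score_classic(list("abcde"), {"b"}) == pytest.approx(0.75)

    def test_disjoint_set_errors(self):
        with pytest.raises(ValidationError):
            enrichment_score_classic(list("abc"), {"z"})

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_oracle_exactly(self, data):
        n = data.draw(st.integers(2, 12))
        ids = [f"i{k}" for k in range(n)]
        size = data.draw(st.integers(1, n - 1))
        members = set(data.draw(st.permutations(ids))[:size])
        assert enrichment_score_classic(ids, members) == pytest.approx(
            oracles.brute_force_es(ids, members), abs=1e-12)

    def test_invariant_to_monotone_score_transform(self):
        """ES depends only on rank order, so exp() on the scores is a no-op."""
        rng = np.random.default_rng(8)
        scores = rng.normal(size=30)
        ids = [f"i{k}" for k in range(30)]
        order1 = [ids[i] for i in np.argsort(-scores)]
        order2 = [ids[i] for i in np.argsort(-np.exp(scores))]
        members = set(ids[:7])
        assert order1 == order2
        assert (enrichment_score_classic(order1, members)
                == enrichment_score_classic(order2, members))

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_under_list_reversal(self, data):
        n = data.draw(st.integers(2, 12))
        ids = [f"i{k}" for k in range(n)]
        size = data.draw(st.integers(1, n - 1))
        members = set(data.draw(st.permutations(ids))[:size])
        es_fwd = enrichment_score_classic(ids, members)
        es_rev = enrichment_score_classic(ids[::-1], members)
        # reversal negates the running sum read backwards; extrema of equal
        # magnitude can differ only in which tie is reported first
        assert abs(es_fwd + es_rev) < 1e-12 or abs(abs(es_fwd) - abs(es_rev)) < 1e-12


class TestKseaRun:
    def test_planted_kinase_recovered(self):
        cfg = PhosphoSimConfig(
            n_responders=12, n_nonresponders=12, n_peptides=400, n_kinases=20,
            substrates_per_kinase=10, planted_kinases=(("K003", 2.5),),
            exclusive_fraction=0.0, seed=21)
        matrix, anns, patterns, _ = simulate_phospho_dataset(cfg)
        results = ksea_run(matrix, anns, patterns, n_perm=200, seed=4)
        best = max(results, key=lambda r: r.nes)
        assert best.kinase_id == "K003"
        assert best.direction == "high_in_responders"
        assert best.fdr_q < 0.20

    def test_results_respect_size_filter(self):
        cfg = PhosphoSimConfig(n_peptides=200, n_kinases=10,
                               substrates_per_kinase=8, seed=5)
        matrix, anns, patterns, _ = simulate_phospho_dataset(cfg)
        for r in ksea_run(matrix, anns, patterns, n_perm=50, seed=1):
            assert 5 < r.set_size < 1000
            assert np.sign(r.nes) == np.sign(r.es) or r.es == 0

    def test_permutation_p_reproducible(self):
        cfg = PhosphoSimConfig(n_peptides=120, n_kinases=8,
                               substrates_per_kinase=8, seed=6)
        matrix, anns, patterns, _ = simulate_phospho_dataset(cfg)
        r1 = ksea_run(matrix, anns, patterns, n_perm=100, seed=2)
        r2 = ksea_run(matrix, anns, patterns, n_perm=100, seed=2)
        assert r1 == r2

    def test_exhaustive_fallback_for_tiny_cohorts(self):
        """With C(n, n_r) below n_perm the label space is enumerated, so the
        result is permutation-noise-free and independent of the seed."""
        cfg = PhosphoSimConfig(n_responders=3, n_nonresponders=3,
                               n_peptides=80, n_kinases=5,
                               substrates_per_kinase=8, seed=7)
        matrix, anns, patterns, _ = simulate_phospho_dataset(cfg)
        r1 = ksea_run(matrix, anns, patterns, n_perm=1000, seed=1)
        r2 = ksea_run(matrix, anns, patterns, n_perm=1000, seed=99)
        assert r1 == r2
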