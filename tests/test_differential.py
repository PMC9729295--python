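"""Per-peptide screen: medians, zero->1 ratios, Monte-Carlo MWW, BH, hits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosphoscreen.differential import (CLOUD_EXCL_NONRESP, CLOUD_EXCL_RESP,
                                        CLOUD_SHARED, benjamini_hochberg,
                                        classify_volcano_hits, median_log2_fc,
                                        mww_exact_test,
                                        mww_permutation_matrix,
                                        mww_permutation_test, normality_gate,
                                        run_differential)
from phosphoscreen.errors import InsufficientDataError, ValidationError

import oracles


class TestNormalityGate:
    def test_lognormal_rejected_as_nonparametric(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(0, 2, size=500))
        assert normality_gate(vals, alpha=0.05) == "nonparametric"

    def test_normal_draws_mostly_parametric(self):
        rng = np.random.default_rng(1)
        calls = [normality_gate(rng.normal(size=500), 0.05) for _ in range(40)]
        # Shapiro-Wilk is a level-alpha test: ~95% of null draws pass
        assert calls.count("parametric") >= 33

    def test_constant_vector_errors(self):
        with pytest.raises(InsufficientDataError, match="variation"):
            normality_gate([3.0] * 10)


class TestMedianLog2Fc:
    def test_zero_responder_median_uses_substitution(self):
        mr, mn, lfc, cloud = median_log2_fc([0, 0, 0, 16, 16, 16],
                                            [True, True, True, False, False, False])
        assert (mr, mn) == (0.0, 16.0)
        assert lfc == -4.0
        assert cloud == CLOUD_EXCL_NONRESP

    def test_equal_medians_shared(self):
        _, _, lfc, cloud = median_log2_fc([8, 8, 8, 8], [True, True, False, False])
        assert lfc == 0.0 and cloud == CLOUD_SHARED

    def test_zero_nonresponder_median(self):
        mr, mn, lfc, cloud = median_log2_fc([8, 8, 0, 0], [True, True, False, False])
        assert lfc == 3.0 and cloud == CLOUD_EXCL_RESP

    def test_order_preserving_in_responder_median(self):
        """Raising the responder median never decreases log2_fc."""
        base = [4, 4, 2, 2]
        mask = [True, True, False, False]
        lfcs = [median_log2_fc([m, m, 2, 2], mask)[2] for m in (0, 1, 2, 8, 64)]
        assert all(a <= b for a, b in zip(lfcs, lfcs[1:]))


class TestMww:
    def test_identical_groups_p_one(self):
        x = [1.0, 2.0, 3.0]
        assert mww_permutation_test(x, x, n_perm=999, seed=0) == 1.0

    def test_worked_case_exact_p(self):
        """x=[1,2,3] vs y=[10,11,12]: all 20 relabelings, exact p = 0.1."""
        assert mww_exact_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_monte_carlo_matches_exact_on_worked_case(self):
        p = mww_permutation_test([1, 2, 3], [10, 11, 12], n_perm=100_000, seed=7)
        assert abs(p - 0.1) <= 3 * np.sqrt(0.1 * 0.9 / 100_000) + 1e-5

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_monte_carlo_matches_enumeration(self, data):
        """MC p within the 3-sigma binomial bound of the exhaustive p,
        including ties and zeros (<= 8 per group)."""
        n1 = data.draw(st.integers(2, 5))
        n2 = data.draw(st.integers(2, 5))
        pool = st.integers(0, 5)
        x = data.draw(st.lists(pool, min_size=n1, max_size=n1))
        y = data.draw(st.lists(pool, min_size=n2, max_size=n2))
        exact = mww_exact_test(x, y)
        n_perm = 4000
        mc = mww_permutation_test(x, y, n_perm=n_perm, seed=42)
        bound = 3 * np.sqrt(exact * (1 - exact) / n_perm) + 2 / n_perm
        assert abs(mc - exact) <= bound

    def test_vectorised_matrix_agrees_with_single_pair(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(10, 1, size=(6, 10))
        vals[rng.random(vals.shape) < 0.2] = 0.0
        mask = np.array([True] * 5 + [False] * 5)
        p_mat = mww_permutation_matrix(vals, mask, n_perm=30_000, seed=9)
        for i in range(vals.shape[0]):
            exact = mww_exact_test(vals[i, mask], vals[i, ~mask])
            bound = 3 * np.sqrt(exact * (1 - exact) / 30_000) + 1e-4
            assert abs(p_mat[i] - exact) <= bound

    def test_seed_reproducibility(self):
        x, y = [1, 5, 3, 8], [2, 9, 4, 7]
        p1 = mww_permutation_test(x, y, n_perm=5000, seed=11)
        p2 = mww_permutation_test(x, y, n_perm=5000, seed=11)
        assert p1 == p2


class TestBenjaminiHochberg:
    def test_hand_computed_step_up_example(self):
        q = benjamini_hochberg([0.002, 0.01, 0.03, 0.04])
        assert np.allclose(q, [0.008, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_one(self):
        assert np.all(benjamini_hochberg([1.0, 1.0, 1.0]) == 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.5])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_matches_independent_step_up_oracle(self, p):
        assert np.allclose(benjamini_hochberg(p), oracles.step_up_bh(p))


class TestVolcanoClassification:
    def _frame(self, lfc, p, q):
        return pd.DataFrame({"peptide_id": ["x"], "log2_fc": [lfc],
                             "p_raw": [p], "q_bh": [q]})

    @pytest.mark.parametrize("lfc,p,q,expect", [
        (5.0, 1e-4, 0.10, True),      # all thresholds cleared
        (4.0, 1e-4, 0.10, False),     # fold change not strictly > 2^4
        (6.0, 0.01, 0.10, False),     # 0.01 >= 10^-2.5 ~ 0.00316
        (-5.0, 1e-4, 0.10, True),     # downregulation counts too
        (5.0, 1e-4, 0.30, False),     # FDR filter
    ])
    def test_strict_thresholds(self, lfc, p, q, expect):
        out = classify_volcano_hits(self._frame(lfc, p, q))
        assert bool(out["is_hit"][0]) is expect
        assert out["volcano_x"][0] == lfc
        assert out["volcano_y"][0] == pytest.approx(-np.log10(p))


class TestRunDifferential:
    def test_exclusive_cloud_geometry(self, small_matrix, small_annotations):
        """A peptide zeroed in nonresponders with responder median m sits at
        exactly x = log2(m)."""
        m = small_matrix
        m.values.loc["pep2"] = [16.0, 16.0, 0.0, 0.0]
        res = run_differential(m, small_annotations, n_perm=200, seed=0)
        row = res[res["peptide_id"] == "pep2"].iloc[0]
        assert row["log2_fc"] == 4.0
        assert row["cloud"] == CLOUD_EXCL_RESP

    def test_arm_filter_insufficient_group(self, small_matrix, small_annotations):
        with pytest.raises(InsufficientDataError):
            run_differential(small_matrix, small_annotations, arm="experimental",
                             n_perm=10, seed=0)
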