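"""Unit and oracle tests for the rank-based statistics.

The heavier cross-validation against independent oracles (statsmodels
rank-ANOVA for the factorial test, first-principles Dunn formula, exact
rank-sum enumeration) lives in test_acceptance.py; here we pin the small
definitional examples and the structural invariants.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from entolat.rankstats import (
    FactorialSample,
    dunn_posthoc,
    eta_squared_label,
    kruskal_eta_squared,
    rank_with_ties,
    scheirer_ray_hare,
    two_proportion_z,
    wilcoxon_ranksum_cc,
)


class TestRankWithTies:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([3, 1, 2], [3, 1, 2]),
            ([5, 5, 7], [1.5, 1.5, 3]),
            ([1], [1]),
            ([2, 2, 2, 2], [2.5, 2.5, 2.5, 2.5]),
        ],
    )
    def test_examples(self, values, expected):
        assert rank_with_ties(values).tolist() == expected

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=50))
    def test_rank_sum_identity_and_scipy_agreement(self, values):
        r = rank_with_ties(values)
        n = len(values)
        assert math.isclose(r.sum(), n * (n + 1) / 2)
        np.testing.assert_allclose(r, sps.rankdata(values))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_with_ties([])


class TestScheirerRayHare:
    def test_hand_example_2x2(self):
        """Values 1..4 with A splitting {1,2}|{3,4} and B splitting {1,3}|{2,4}:
        ranks 1-4, SS_total = 5, MS_total = 5/3, so H_A = 2.4, H_B = 0.6,
        H_AB = 0."""
        s = scheirer_ray_hare(
            FactorialSample(
                np.array([1.0, 2.0, 3.0, 4.0]),
                np.array(["a1", "a1", "a2", "a2"]),
                np.array(["b1", "b2", "b1", "b2"]),
            )
        )
        assert s.H_a == pytest.approx(2.4, abs=1e-9)
        assert s.H_b == pytest.approx(0.6, abs=1e-9)
        assert s.H_ab == pytest.approx(0.0, abs=1e-9)
        assert (s.df_a, s.df_b, s.df_ab) == (1, 1, 1)

    def test_all_tied_degenerate(self):
        with pytest.warns(UserWarning, match="tied"):
            s = scheirer_ray_hare(
                FactorialSample(
                    np.full(8, 3.0),
                    np.repeat(["a1", "a2"], 4),
                    np.tile(["b1", "b2"], 4),
                )
            )
        assert math.isnan(s.H_a) and math.isnan(s.H_b) and math.isnan(s.H_ab)
        assert s.p_a == s.p_b == s.p_ab == 1.0

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="empty cell"):
            scheirer_ray_hare(
                FactorialSample(
                    np.arange(6.0),
                    np.array(["a1"] * 3 + ["a2"] * 3),
                    np.array(["b1", "b1", "b2", "b1", "b1", "b1"][::-1]),
                )
            )

    def test_reduces_to_kruskal_wallis_with_constant_factor(self):
        """With factor B constant, H_A equals the tie-corrected Kruskal-Wallis
        statistic for the A grouping."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            groups = rng.integers(2, 5)
            sizes = rng.integers(3, 9, size=groups)
            vals = [rng.integers(0, 6, size=n).astype(float) for n in sizes]
            if len(np.unique(np.concatenate(vals))) < 2:
                continue
            fa = np.repeat([f"g{i}" for i in range(groups)], sizes)
            s = scheirer_ray_hare(
                FactorialSample(np.concatenate(vals), fa, np.full(sizes.sum(), "b"))
            )
            kw_h, _ = sps.kruskal(*vals)
            assert s.H_a == pytest.approx(kw_h, abs=1e-9)
            assert s.H_b == 0.0 and s.p_b == 1.0

    def test_monotone_invariance(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=24)
        fa = np.repeat(["a1", "a2"], 12)
        fb = np.tile(np.repeat(["b1", "b2"], 6), 2)
        s1 = scheirer_ray_hare(FactorialSample(v, fa, fb))
        s2 = scheirer_ray_hare(FactorialSample(np.exp(v), fa, fb))
        assert s1.H_a == pytest.approx(s2.H_a, abs=1e-9)
        assert s1.H_ab == pytest.approx(s2.H_ab, abs=1e-9)


class TestEtaSquared:
    def test_null_expectation_is_zero(self):
        assert kruskal_eta_squared(1.0, k=2, n=30)[0] == pytest.approx(0.0)

    def test_formula_value_and_label(self):
        eta2, label = kruskal_eta_squared(5.0, k=2, n=100)
        assert eta2 == pytest.approx(4 / 98, abs=1e-12)
        assert label == "small"

    def test_moderate_band(self):
        assert eta_squared_label(0.08) == "moderate"
        assert eta_squared_label(0.14) == "large"
        assert eta_squared_label(0.005) == "negligible"

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kruskal_eta_squared(1.0, k=2, n=2)
        with pytest.raises(ValueError):
            kruskal_eta_squared(-1.0, k=2, n=10)


class TestDunn:
    def test_identical_groups_null(self):
        res = dunn_posthoc([1, 2, 3, 1, 2, 3], ["g1"] * 3 + ["g2"] * 3, [("g1", "g2")])
        c = res.comparisons[0]
        assert c.z == pytest.approx(0.0)
        assert c.p_raw == pytest.approx(1.0)

    def test_antisymmetry(self):
        vals = [4.0, 1.0, 3.0, 9.0, 2.0, 2.0, 7.0, 5.0]
        groups = ["a", "a", "a", "b", "b", "b", "c", "c"]
        res = dunn_posthoc(vals, groups, [("a", "b"), ("b", "a")])
        assert res.comparisons[0].z == pytest.approx(-res.comparisons[1].z)
        assert res.comparisons[0].p_raw == pytest.approx(res.comparisons[1].p_raw)

    def test_bonferroni_scaling(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=12)
        groups = np.repeat(["a", "b", "c"], 4)
        res = dunn_posthoc(vals, groups, [("a", "b"), ("a", "c"), ("b", "c")])
        for c in res.comparisons:
            assert c.p_bonferroni == pytest.approx(min(1.0, 3 * c.p_raw))

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_posthoc([1, 2], ["a", "b"], [("a", "z")])


def exact_ranksum_p(x, y) -> float:
    """Exact two-sided rank-sum p by enumerating all rank assignments.

    Independent oracle for tie-free samples with n1 + n2 small.
    """
    n1, N = len(x), len(x) + len(y)
    ranks = sps.rankdata(np.concatenate([x, y]))
    w_obs = ranks[:n1].sum()
    mean = n1 * (N + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(1, N + 1), n1):
        total += 1
        if abs(sum(combo) - mean) >= abs(w_obs - mean) - 1e-12:
            count += 1
    return count / total


class TestWilcoxonRankSumCC:
    def test_identical_samples(self):
        _, p = wilcoxon_ranksum_cc([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_small_sample_vs_exact_enumeration(self):
        """{1,2,3} vs {10,11,12}: exact two-sided p is 2/20 = 0.1; the
        continuity-corrected normal approximation lands close to it."""
        x, y = [1.0, 2.0, 3.0], [10.0, 11.0, 12.0]
        assert exact_ranksum_p(x, y) == pytest.approx(0.1)
        _, p = wilcoxon_ranksum_cc(x, y)
        assert abs(p - 0.1) < 0.03

    def test_matches_scipy_asymptotic(self):
        """Independent route: scipy's Mann-Whitney U with continuity
        correction gives the same p on tie-free and tied data."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            n1, n2 = rng.integers(3, 30, size=2)
            x = rng.integers(0, 8, size=n1).astype(float)
            y = rng.integers(0, 8, size=n2).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            _, p = wilcoxon_ranksum_cc(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_ranksum_cc([], [1.0])


class TestTwoProportionZ:
    def test_equal_proportions(self):
        z, p, degenerate = two_proportion_z(10, 40, 5, 20)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert not degenerate

    def test_pooled_formula_value(self):
        z, _, _ = two_proportion_z(10, 20, 5, 20)
        assert z == pytest.approx(1.633, abs=5e-4)

    def test_degenerate_pooled_proportion(self):
        z, p, degenerate = two_proportion_z(0, 10, 0, 10)
        assert degenerate and z == 0.0 and p == 1.0

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            two_proportion_z(5, 4, 1, 10)
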