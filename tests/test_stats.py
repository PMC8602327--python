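"""Statistical primitives against hand computations and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from metanet.stats import (
    bh_adjust,
    chi_square_independence,
    pearson_correlation_test,
    rank_sum_test,
    trend_test,
    two_proportion_test,
)


class TestTwoProportion:
    def test_published_liver_metastasis_fractions(self):
        # 143/180 vs 263/329 liver-metastasis fractions agree: p = 0.89
        res = two_proportion_test(143, 180, 263, 329)
        assert res.p_value == pytest.approx(0.89, abs=0.005)

    def test_identical_proportions_give_z_zero(self):
        res = two_proportion_test(10, 20, 10, 20)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_extreme_separation_closed_form(self):
        # pooled p-hat = 0.5 -> z = (1 - 0) / sqrt(0.25 * 2/50) = 10
        res = two_proportion_test(50, 50, 0, 50)
        assert res.statistic == pytest.approx(10.0, abs=1e-9)
        assert res.p_value == pytest.approx(2 * sps.norm.sf(10), rel=1e-6)

    def test_z_squared_equals_chi2_identity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n1, n2 = rng.integers(5, 80, size=2)
            k1 = rng.integers(1, n1)
            k2 = rng.integers(1, n2)
            z = two_proportion_test(int(k1), int(n1), int(k2), int(n2)).statistic
            table = np.array([[k1, k2], [n1 - k1, n2 - k2]])
            chi2 = chi_square_independence(table).statistic
            assert z ** 2 == pytest.approx(chi2, abs=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            two_proportion_test(1, 0, 1, 2)
        with pytest.raises(ValueError):
            two_proportion_test(5, 3, 1, 2)


class TestChiSquare:
    def test_hand_computed_2x4(self):
        # mutants (30,10,10,10) of 100 per site; expected 15/site -> 23.53
        table = np.array([[30, 10, 10, 10], [70, 90, 90, 90]])
        res = chi_square_independence(table)
        assert res.statistic == pytest.approx(23.53, abs=0.005)
        assert res.df == 3

    def test_uniform_fractions_give_zero(self):
        res = chi_square_independence(np.array([[5, 5, 5], [20, 20, 20]]))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_observed_expected_loop(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            table = rng.integers(1, 50, size=(2, 4)).astype(float)
            res = chi_square_independence(table)
            col = table.sum(axis=0)
            row_frac = table.sum(axis=1) / table.sum()
            chi2 = 0.0
            for i in range(2):
                for j in range(4):
                    e = col[j] * row_frac[i]
                    chi2 += (table[i, j] - e) ** 2 / e
            assert res.statistic == pytest.approx(chi2, abs=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="site"):
            chi_square_independence(np.array([[0, 5], [0, 5]]))


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_single_and_equal_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_dominates_input_and_preserves_order(self, p):
        q = bh_adjust(p)
        assert (q >= np.asarray(p) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
        # order of evidence is preserved: smaller p never gets a larger q
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_matches_hand_step_up_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = rng.random(12)
            m = p.size
            order = np.argsort(p)
            q_sorted = np.minimum.accumulate(
                (p[order] * m / np.arange(1, m + 1))[::-1]
            )[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(q_sorted, 1.0)
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=15), st.randoms())
    @settings(max_examples=30, deadline=None)
    def test_permutation_equivariant(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        q = bh_adjust(p)
        q_perm = bh_adjust([p[i] for i in perm])
        np.testing.assert_allclose(q_perm, [q[i] for i in perm], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestRankSum:
    def test_identical_samples(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3], sided="one_sided")
        assert res.p_value >= 0.5

    def test_full_separation_u_statistic(self):
        # all of y above x: U for x is 0; exact enumeration p = 1/C(6,3) = 0.05
        res = rank_sum_test([1, 2, 3], [10, 11, 12], sided="one_sided")
        assert res.statistic == 0.0
        exact_p = 1 / 20
        # normal approximation at n = 3 vs the enumeration oracle: loose only
        assert res.p_value == pytest.approx(exact_p, abs=0.03)

    def test_u_matches_exact_enumeration(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            u = rank_sum_test(x, y).statistic
            u_brute = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
            assert u == pytest.approx(u_brute, abs=1e-9)

    def test_all_tied_warns_p_one(self):
        res = rank_sum_test([1.0, 1.0], [1.0, 1.0])
        assert res.p_value == 1.0


class TestTrend:
    def test_equal_proportions_z_zero(self):
        res = trend_test([10, 20, 30], [100, 200, 300])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_trend_significant(self):
        res = trend_test([100, 200, 300, 400], [1000, 1000, 1000, 1000])
        assert res.p_value < 1e-6
        assert res.statistic > 0

    def test_reversal_flips_sign(self):
        up = trend_test([5, 10, 20], [50, 50, 50])
        down = trend_test([20, 10, 5], [50, 50, 50])
        assert up.statistic == pytest.approx(-down.statistic, abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            trend_test([1, 2], [10, 10, 10])


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res, r = pearson_correlation_test(x, 2 * x)
        assert r == pytest.approx(1.0)
        res, r = pearson_correlation_test(x, -x)
        assert r == pytest.approx(-1.0)

    def test_t_statistic_closed_form(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=71)
        y = 0.9 * x + 0.4 * rng.normal(size=71)
        res, r = pearson_correlation_test(x, y)
        t = r * np.sqrt((71 - 2) / (1 - r * r))
        assert res.statistic == pytest.approx(t, rel=1e-9)
        assert res.df == 69
        if r > 0.9:
            assert res.p_value < 1e-4

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation_test([1, 1, 1], [1, 2, 3])
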