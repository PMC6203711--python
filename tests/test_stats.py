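"""Unit and property tests for the statistical core.

Exact tests are checked against brute-force enumeration oracles written
directly from the definitions (math.comb combinatorics, exhaustive rank
assignments), independent of the implementation's scipy-based path.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nashsom import stats

# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------


def fisher_oracle(a, b, c, d, alternative):
    """Enumerate every 2x2 table with the observed margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {x: math.comb(r1, x) * math.comb(n - r1, c1 - x) / denom
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    if alternative == "greater":
        return sum(p for x, p in probs.items() if x >= a)
    if alternative == "less":
        return sum(p for x, p in probs.items() if x <= a)
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7)))


def hypergeom_oracle(k, K, n, N):
    denom = math.comb(N, n)
    return sum(math.comb(K, x) * math.comb(N - K, n - x) / denom
               for x in range(k, min(K, n) + 1))


def ranksum_oracle(nx, ny, w, alternative):
    """Exhaust all assignments of ranks 1..nx+ny to the first sample."""
    n = nx + ny
    sums = [sum(c) for c in itertools.combinations(range(1, n + 1), nx)]
    total = len(sums)
    n_le = sum(s <= w + 1e-9 for s in sums)
    n_ge = sum(s >= w - 1e-9 for s in sums)
    if alternative == "less":
        return n_le / total
    if alternative == "greater":
        return n_ge / total
    return min(1.0, 2 * min(n_le, n_ge) / total)


# ---------------------------------------------------------------------------
# Fisher
# ---------------------------------------------------------------------------


class TestFisher:
    def test_symmetric_table_is_null(self):
        assert stats.fisher_exact(5, 5, 5, 5).p_value == pytest.approx(1.0)

    def test_extreme_table_equals_single_point_mass(self):
        r = stats.fisher_exact(10, 0, 0, 10)
        assert r.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-12)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_enumeration_on_unbalanced_table(self, alternative):
        r = stats.fisher_exact(12, 3, 2, 38, alternative=alternative)
        assert r.p_value == pytest.approx(
            fisher_oracle(12, 3, 2, 38, alternative), rel=1e-9)

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8), st.integers(0, 8),
           st.sampled_from(["two-sided", "greater", "less"]))
    def test_matches_enumeration_for_small_tables(self, a, b, c, d, alternative):
        r = stats.fisher_exact(a, b, c, d, alternative=alternative)
        assert 0.0 <= r.p_value <= 1.0
        if (a + b) and (c + d) and (a + c) and (b + d):
            assert r.p_value == pytest.approx(
                fisher_oracle(a, b, c, d, alternative), rel=1e-9)
        else:
            assert r.p_value == 1.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            stats.fisher_exact(-1, 2, 3, 4)

    def test_type_one_error_conservative_under_null(self):
        # exact conditional test never exceeds the nominal level
        rng = np.random.default_rng(7)
        n1 = n2 = 25
        rej = 0
        reps = 10_000
        x1 = rng.binomial(n1, 0.2, size=reps)
        x2 = rng.binomial(n2, 0.2, size=reps)
        for k1, k2 in zip(x1, x2):
            p = stats.fisher_exact(int(k1), n1 - int(k1), int(k2), n2 - int(k2)).p_value
            rej += p < 0.05
        assert rej / reps <= 0.05


# ---------------------------------------------------------------------------
# Binomial tail
# ---------------------------------------------------------------------------


class TestBinomTail:
    @pytest.mark.parametrize("k,n,f,expected", [
        (5, 5, 0.1, 1.0),                       # full support
        (0, 5, 0.1, 0.9**5),                    # closed form (1-f)^n
        (1, 10, 0.1, 0.9**10 + 10 * 0.1 * 0.9**9),
    ])
    def test_lower_tail_values(self, k, n, f, expected):
        assert stats.binom_cdf_test(k, n, f).p_value == pytest.approx(expected, rel=1e-9)

    def test_upper_orientation_complements(self):
        lo = stats.binom_cdf_test(3, 20, 0.1, orientation="lower").p_value
        hi = stats.binom_cdf_test(4, 20, 0.1, orientation="upper").p_value
        assert lo + hi == pytest.approx(1.0, rel=1e-12)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            stats.binom_cdf_test(6, 5, 0.1)

    @given(st.integers(0, 20), st.integers(0, 20), st.sampled_from([0.1, 0.3, 0.5]))
    def test_matches_direct_summation(self, k, n, f):
        if k > n:
            return
        expected = sum(math.comb(n, j) * f**j * (1 - f) ** (n - j) for j in range(k + 1))
        assert stats.binom_cdf_test(k, n, f).p_value == pytest.approx(
            min(1.0, expected), rel=1e-9)


# ---------------------------------------------------------------------------
# Wilcoxon rank sum
# ---------------------------------------------------------------------------


class TestRankSum:
    def test_minimal_rank_sum_exact(self):
        assert stats.wilcoxon_rank_sum([1, 2], [3, 4], "less").p_value == \
            pytest.approx(1 / 6)

    def test_maximal_rank_sum_exact(self):
        assert stats.wilcoxon_rank_sum([3, 4], [1, 2], "less").p_value == \
            pytest.approx(1.0)

    @pytest.mark.parametrize("nx,ny", [(3, 3), (4, 5), (6, 6)])
    def test_exact_path_matches_enumeration(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        xs = rng.permutation(np.arange(1.0, nx + ny + 1))[:nx]
        ys = np.setdiff1d(np.arange(1.0, nx + ny + 1), xs)
        w = xs.sum()
        for alt in ("two-sided", "greater", "less"):
            got = stats.wilcoxon_rank_sum(xs, ys, alt)
            assert "exact" in got.method
            assert got.p_value == pytest.approx(ranksum_oracle(nx, ny, w, alt), rel=1e-9)

    def test_approximation_close_to_enumeration_at_8v8(self):
        rng = np.random.default_rng(0)
        xs = rng.normal(size=8)
        ys = rng.normal(size=8)
        w = float(np.argsort(np.argsort(np.concatenate([xs, ys]))).astype(float)[:8].sum() + 8)
        for alt in ("two-sided", "greater", "less"):
            got = stats.wilcoxon_rank_sum(xs, ys, alt)
            assert "approximation" in got.method
            assert abs(got.p_value - ranksum_oracle(8, 8, w, alt)) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            stats.wilcoxon_rank_sum([], [1.0])

    def test_all_tied_values_give_p_one(self):
        r = stats.wilcoxon_rank_sum([5] * 10, [5] * 10)
        assert r.p_value == 1.0


# ---------------------------------------------------------------------------
# Hypergeometric over-representation
# ---------------------------------------------------------------------------


class TestHypergeom:
    def test_zero_overlap_is_certain(self):
        assert stats.hypergeom_overrep(0, 5, 5, 20).p_value == pytest.approx(1.0)

    def test_complete_overlap_single_table(self):
        assert stats.hypergeom_overrep(5, 5, 5, 20).p_value == \
            pytest.approx(1 / math.comb(20, 5), rel=1e-12)

    def test_complement_enumeration(self):
        assert stats.hypergeom_overrep(1, 2, 2, 10).p_value == \
            pytest.approx(17 / 45, rel=1e-12)

    @given(st.integers(1, 20), st.data())
    def test_matches_enumeration(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, K + n - N), min(K, n)))
        assert stats.hypergeom_overrep(k, K, n, N).p_value == pytest.approx(
            hypergeom_oracle(k, K, n, N), rel=1e-9)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            stats.hypergeom_overrep(3, 2, 5, 10)


# ---------------------------------------------------------------------------
# BH adjustment
# ---------------------------------------------------------------------------


class TestBH:
    def test_single_p_unchanged(self):
        assert stats.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        np.testing.assert_allclose(stats.bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.uniform(size=40)
        np.testing.assert_allclose(stats.bh_adjust(p),
                                   multipletests(p, method="fdr_bh")[1])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_dominates_raw_and_idempotent_and_equivariant(self, pvals):
        adj = stats.bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0)
        # permutation equivariance
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(pvals))
        np.testing.assert_allclose(stats.bh_adjust(np.asarray(pvals)[perm]), adj[perm])

    @pytest.mark.parametrize("fixpoint", [
        [0.3, 0.3, 0.3, 0.3],          # constant vectors are BH fixpoints
        [0.0, 0.0, 0.7],               # zeros below a single adjusted value
        [1.0, 1.0],
    ])
    def test_idempotent_on_fixpoint_inputs(self, fixpoint):
        np.testing.assert_allclose(stats.bh_adjust(fixpoint), fixpoint)

    def test_monotone_along_sorted_raw_order(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=25)
        adj = stats.bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


class TestTTest:
    def test_identical_groups_null(self):
        r = stats.t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_published_burden_summary_is_significant(self):
        # non-synonymous burden summaries of the two diet groups
        r = stats.t_test_from_stats(335, 84, 5, 43, 13, 3)
        assert r.p_value < 0.05
        # ...and remains so if the printed dispersion were a standard error
        r_se = stats.t_test_from_stats(335, 84 * math.sqrt(5), 5,
                                       43, 13 * math.sqrt(3), 3)
        assert r_se.p_value < 0.05

    def test_raw_and_summary_paths_identical(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 9), rng.normal(1, 2, 6)
        raw = stats.t_test(x, y)
        summ = stats.t_test_from_stats(x.mean(), x.std(ddof=1), x.size,
                                       y.mean(), y.std(ddof=1), y.size)
        assert raw.statistic == pytest.approx(summ.statistic)
        assert raw.p_value == pytest.approx(summ.p_value)
        assert raw.df == pytest.approx(summ.df)

    def test_matches_scipy_welch_and_paired(self):
        from scipy import stats as sps
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 12), rng.normal(0.5, 2, 12)
        assert stats.t_test(x, y).p_value == pytest.approx(
            sps.ttest_ind(x, y, equal_var=False).pvalue)
        assert stats.t_test(x, y, paired=True).p_value == pytest.approx(
            sps.ttest_rel(x, y).pvalue)

    def test_zero_variance_conventions(self):
        r = stats.t_test([2.0, 2.0], [2.0, 2.0])
        assert r.p_value == 1.0
        with pytest.raises(ValueError):
            stats.t_test([2.0, 2.0], [3.0, 3.0])

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(11)
        reps, n = 10_000, 20
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=(reps, n))
        rej = sum(stats.t_test(x[i], y[i]).p_value < 0.05 for i in range(reps))
        assert abs(rej / reps - 0.05) <= 0.01


# ---------------------------------------------------------------------------
# chi-square
# ---------------------------------------------------------------------------


class TestChiSquare:
    def test_independent_table_null(self):
        r = stats.chi_square_2x2(10, 10, 10, 10)
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_closed_form(self):
        a, b, c, d = 5, 32, 26, 327
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / \
            ((a + b) * (c + d) * (a + c) * (b + d))
        assert stats.chi_square_2x2(a, b, c, d).statistic == pytest.approx(expected)

    def test_statistic_scales_with_counts(self):
        s1 = stats.chi_square_2x2(5, 10, 15, 20).statistic
        s2 = stats.chi_square_2x2(10, 20, 30, 40).statistic
        assert s2 == pytest.approx(2 * s1)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            stats.chi_square_2x2(0, 0, 5, 5)
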