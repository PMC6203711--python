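"""Statistical tests underpinning the somatic filter cascade and cohort analyses.

Each test here pins down a precise convention — sidedness, tail orientation,
tie handling — because downstream pass/fail decisions compare raw p-values
against fixed cutoffs, and a silent change of orientation would flip filter
verdicts.  The numerical primitives (hypergeometric/binomial/t distributions)
come from scipy; the conditioning, enumeration bounds and corrections are
defined here and verified against brute-force enumeration oracles in the
test suite.

Conventions
-----------
* ``alternative`` is one of ``"two-sided"``, ``"greater"``, ``"less"``.
* For 2x2 tables laid out as ``[[a, b], [c, d]]`` the conditional
  distribution is on cell ``a``; ``"greater"`` means *a larger than expected
  under independence* (odds ratio > 1).
* The binomial sequencing-error screen is lower-tail by default:
  ``p = P(X <= k)`` under ``Binomial(n, f)``, so sites with abundant variant
  support score near 1 and survive a ``p > alpha`` pass rule, while sites
  whose support is improbably *low* for a real variant fail.  The
  orientation is an explicit argument because the screen's published
  description does not fix it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "TestResult",
    "fisher_exact",
    "binom_cdf_test",
    "wilcoxon_rank_sum",
    "hypergeom_overrep",
    "bh_adjust",
    "t_test",
    "t_test_from_stats",
    "chi_square_2x2",
]

_ALTERNATIVES = ("two-sided", "greater", "less")

# exact Wilcoxon enumeration is used up to this combined sample size
EXACT_RANKSUM_MAX_N = 12


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        Test statistic (odds ratio, rank sum, t, chi-square, or the observed
        count for count-based exact tests).
    p_value : float
        p-value in [0, 1] under the stated alternative.
    alternative : str
        One of ``"two-sided"``, ``"greater"``, ``"less"``.
    method : str
        Human-readable label of the procedure actually used.
    df : float or None
        Degrees of freedom, where the method has one.
    """

    statistic: float
    p_value: float
    alternative: str
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(
            f"alternative must be one of {_ALTERNATIVES}, got {alternative!r}"
        )


def _check_counts(*counts: float) -> None:
    for c in counts:
        if c < 0 or c != int(c):
            raise ValueError(f"counts must be non-negative integers, got {c!r}")


def fisher_exact(a: int, b: int, c: int, d: int,
                 alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on the 2x2 table ``[[a, b], [c, d]]``.

    Conditions on both margins; cell ``a`` follows a hypergeometric
    distribution over its support.  The two-sided p-value is the sum of the
    probabilities of all tables no more probable than the observed one
    (the standard "probability method").

    ``greater`` is the tail where ``a`` exceeds its conditional expectation
    (odds ratio > 1); ``less`` the opposite tail.  Degenerate margins (an
    empty row or column) leave a single achievable table, so p = 1.
    """
    _check_alternative(alternative)
    _check_counts(a, b, c, d)
    a, b, c, d = int(a), int(b), int(c), int(d)
    n_total = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n_total == 0 or row1 == 0 or row1 == n_total or col1 == 0 or col1 == n_total:
        odds = _sample_odds_ratio(a, b, c, d)
        return TestResult(odds, 1.0, alternative, "Fisher exact (degenerate margin)")

    lo = max(0, row1 + col1 - n_total)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = _sps.hypergeom.pmf(support, n_total, row1, col1)
    p_obs = pmf[a - lo]

    if alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        # tolerance guards against ties in pmf broken by rounding
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    p = min(1.0, p)
    return TestResult(_sample_odds_ratio(a, b, c, d), p, alternative, "Fisher exact")


def _sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def binom_cdf_test(k: int, n: int, f: float,
                   orientation: str = "lower") -> TestResult:
    """Binomial tail test of ``k`` successes in ``n`` trials at null rate ``f``.

    ``orientation="lower"`` (default) returns ``P(X <= k)``;
    ``orientation="upper"`` returns ``P(X >= k)``.  See the module docstring
    for why the sequencing-error screen uses the lower tail.
    """
    _check_counts(k, n)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if not 0.0 < f < 1.0:
        raise ValueError(f"null rate f must be in (0, 1), got {f}")
    if orientation == "lower":
        p = float(_sps.binom.cdf(k, n, f))
        alt = "less"
    elif orientation == "upper":
        p = float(_sps.binom.sf(k - 1, n, f))
        alt = "greater"
    else:
        raise ValueError(f"orientation must be 'lower' or 'upper', got {orientation!r}")
    return TestResult(float(k), min(1.0, p), alt, f"binomial tail test (f={f})")


def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranks and the tie-group sizes of a pooled sample."""
    ranks = _sps.rankdata(values, method="average")
    _, counts = np.unique(values, return_counts=True)
    return ranks, counts


def wilcoxon_rank_sum(xs, ys, alternative: str = "two-sided") -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test on two independent samples.

    The statistic is the rank sum of ``xs`` in the pooled mid-ranked sample.
    For combined sample sizes up to 12 with no ties the p-value is computed
    by exhaustive enumeration of all rank assignments; otherwise a normal
    approximation with tie-corrected variance and a 0.5 continuity
    correction is used.
    """
    _check_alternative(alternative)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size == 0 or ys.size == 0:
        raise ValueError("both samples must be non-empty")
    nx, ny = xs.size, ys.size
    n = nx + ny
    pooled = np.concatenate([xs, ys])
    ranks, tie_counts = _rank_with_ties(pooled)
    w = float(ranks[:nx].sum())
    has_ties = bool((tie_counts > 1).any())

    if n <= EXACT_RANKSUM_MAX_N and not has_ties:
        # ranks are exactly 1..n; enumerate every way to assign nx of them
        all_ranks = range(1, n + 1)
        total = math.comb(n, nx)
        n_le = n_ge = 0
        for combo in itertools.combinations(all_ranks, nx):
            s = sum(combo)
            if s <= w + 1e-9:
                n_le += 1
            if s >= w - 1e-9:
                n_ge += 1
        if alternative == "less":
            p = n_le / total
        elif alternative == "greater":
            p = n_ge / total
        else:
            p = min(1.0, 2.0 * min(n_le, n_ge) / total)
        return TestResult(w, p, alternative, "Wilcoxon rank-sum (exact)")

    mean = nx * (n + 1) / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = nx * ny / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        # all observations identical: no evidence either way
        return TestResult(w, 1.0, alternative, "Wilcoxon rank-sum (degenerate)")
    sd = math.sqrt(var)
    if alternative == "less":
        p = float(_sps.norm.cdf((w - mean + 0.5) / sd))
    elif alternative == "greater":
        p = float(_sps.norm.sf((w - mean - 0.5) / sd))
    else:
        z = (abs(w - mean) - 0.5) / sd
        p = float(2.0 * _sps.norm.sf(max(z, 0.0)))
    return TestResult(w, min(1.0, p), alternative,
                      "Wilcoxon rank-sum (normal approximation, tie-corrected)")


def hypergeom_overrep(k: int, K: int, n: int, N: int) -> TestResult:
    """Over-representation p-value ``P(X >= k)``, X ~ Hypergeometric(N, K, n).

    ``N`` is the universe size, ``K`` the gene-set size, ``n`` the query-list
    size and ``k`` the observed overlap.
    """
    _check_counts(k, K, n, N)
    if K > N or n > N:
        raise ValueError(f"set size K={K} and list size n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ValueError(f"overlap k={k} exceeds min(K, n)={min(K, n)}")
    p = float(_sps.hypergeom.sf(k - 1, N, K, n))
    return TestResult(float(k), min(1.0, p), "greater", "hypergeometric over-representation")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Adjusted values are monotone along the sorted raw p-values and capped at
    1; the procedure controls the false discovery rate for independent or
    positively dependent tests.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adj
    return out


def t_test_from_stats(mean1: float, sd1: float, n1: int,
                      mean2: float, sd2: float, n2: int,
                      equal_var: bool = False) -> TestResult:
    """Two-sample t-test from summary statistics (two-sided).

    Welch's unequal-variance form is the default; ``equal_var=True`` pools
    the variances.  If both groups have zero variance the test is
    conventionally p = 1 when the means agree, and an error otherwise (no
    finite t exists).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 observations")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2, sd2**2
    if v1 == 0 and v2 == 0:
        if mean1 == mean2:
            return TestResult(0.0, 1.0, "two-sided", "t-test (degenerate: no variance)",
                              df=float(n1 + n2 - 2))
        raise ValueError("zero variance in both groups with unequal means")
    if equal_var:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
        method = "Student t-test (pooled)"
    else:
        se2 = v1 / n1 + v2 / n2
        se = math.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        method = "Welch t-test"
    t = (mean1 - mean2) / se
    p = float(2.0 * _sps.t.sf(abs(t), df))
    return TestResult(t, min(1.0, p), "two-sided", method, df=float(df))


def t_test(x, y, paired: bool = False, equal_var: bool = False) -> TestResult:
    """Two-sided t-test on raw data.

    Unpaired comparisons default to Welch's form and route through
    :func:`t_test_from_stats`, so summary-statistic and raw-data calls are
    numerically identical on matching inputs.  ``paired=True`` performs a
    one-sample t-test on the within-pair differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        if x.size < 2:
            raise ValueError("need at least 2 pairs")
        d = x - y
        sd = float(d.std(ddof=1))
        n = d.size
        if sd == 0:
            if float(d.mean()) == 0:
                return TestResult(0.0, 1.0, "two-sided",
                                  "paired t-test (degenerate: no variance)",
                                  df=float(n - 1))
            raise ValueError("zero variance of differences with nonzero mean")
        t = float(d.mean()) / (sd / math.sqrt(n))
        p = float(2.0 * _sps.t.sf(abs(t), n - 1))
        return TestResult(t, min(1.0, p), "two-sided", "paired t-test", df=float(n - 1))
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    return t_test_from_stats(float(x.mean()), float(x.std(ddof=1)), x.size,
                             float(y.mean()), float(y.std(ddof=1)), y.size,
                             equal_var=equal_var)


def chi_square_2x2(a: int, b: int, c: int, d: int,
                   continuity: bool = False) -> TestResult:
    """Pearson chi-square test of independence on ``[[a, b], [c, d]]``, 1 df.

    ``continuity=True`` applies the Yates correction.  A zero margin leaves
    the statistic undefined and raises.
    """
    _check_counts(a, b, c, d)
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if n == 0 or 0 in (r1, r2, c1, c2):
        raise ValueError("chi-square undefined: a table margin is zero")
    diff = abs(a * d - b * c)
    if continuity:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff**2 / (r1 * r2 * c1 * c2)
    p = float(_sps.chi2.sf(stat, 1))
    method = "chi-square (Yates)" if continuity else "chi-square"
    return TestResult(float(stat), min(1.0, p), "two-sided", method, df=1.0)
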