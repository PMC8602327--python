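"""Statistical primitives shared across the framework.

All tests return a :class:`TestResult` carrying the raw statistic, degrees of
freedom where defined, and the p-value.  Normal approximations are used
throughout (the cohort screens operate on hundreds to thousands of samples);
no exact small-sample modes are provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TestResult",
    "two_proportion_test",
    "chi_square_independence",
    "bh_adjust",
    "rank_sum_test",
    "trend_test",
    "pearson_correlation_test",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    Attributes
    ----------
    statistic : float
        The test statistic (z, chi-squared, U, or t depending on the test).
    p_value : float
        The p-value, in [0, 1].
    df : int, optional
        Degrees of freedom where the reference distribution has any.
    sidedness : str
        ``"two_sided"`` or ``"one_sided"``.
    """

    statistic: float
    p_value: float
    df: Optional[int] = None
    sidedness: str = "two_sided"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")
        if self.df is not None and self.df < 1:
            raise ValueError(f"degrees of freedom must be >= 1, got {self.df}")


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, sided: str = "two_sided"
) -> TestResult:
    """Pooled two-proportion z-test, without continuity correction.

    Compares success fractions ``k1/n1`` and ``k2/n2`` using the pooled
    standard error.  The one-sided alternative is ``p1 > p2``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0.0:
        z = 0.0
    else:
        z = (p1 - p2) / se
    if sided == "two_sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif sided == "one_sided":
        p = sps.norm.sf(z)
    else:
        raise ValueError(f"unknown sidedness {sided!r}")
    logger.debug("two_proportion_test z=%.6g p=%.6g", z, p)
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)), sidedness=sided)


def chi_square_independence(table: np.ndarray) -> TestResult:
    """Pearson chi-squared test of independence on a 2 x K count table.

    Expected counts are (column total) x (pooled row fraction), i.e. each
    site's expected mutant count under the average fraction across sites.
    df = K - 1.  No continuity correction.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("table must be 2 x K with K >= 2")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    if (col == 0).any():
        empty = list(np.where(col == 0)[0])
        raise ValueError(f"zero column marginal at site index {empty}")
    if (row == 0).any():
        raise ValueError("zero row marginal (no mutants or no wildtype overall)")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
    logger.debug("chi_square_independence chi2=%.6g df=%d p=%.6g", chi2, df, p)
    return TestResult(statistic=float(chi2), p_value=float(p), df=int(df))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], sided: str = "two_sided"
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U) test, normal approximation.

    Uses midranks with tie correction and no continuity correction.  The
    statistic reported is U for the first sample ``x``; the one-sided
    alternative is "y tends to be greater than x" (i.e. small U).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.unique(np.concatenate([x, y])).size == 1:
        logger.warning("rank_sum_test: all values tied across both groups; p = 1")
        return TestResult(statistic=x.size * y.size / 2.0, p_value=1.0, sidedness=sided)
    alternative = "less" if sided == "one_sided" else "two-sided"
    res = sps.mannwhitneyu(
        x, y, alternative=alternative, method="asymptotic", use_continuity=False
    )
    logger.debug("rank_sum_test U=%.6g p=%.6g", res.statistic, res.pvalue)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue), sidedness=sided)


def trend_test(
    k_vector: Sequence[int],
    n_vector: Sequence[int],
    scores: Optional[Sequence[float]] = None,
) -> TestResult:
    """Cochran-Armitage test for a linear trend in proportions.

    ``k_vector[i]`` successes out of ``n_vector[i]`` in ordered group *i*
    with numeric score ``scores[i]`` (default 0, 1, 2, ...).  Returns the
    signed z statistic (positive = proportion increases with score) and a
    two-sided p-value.
    """
    k = np.asarray(k_vector, dtype=float)
    n = np.asarray(n_vector, dtype=float)
    if k.shape != n.shape:
        raise ValueError("k_vector and n_vector must have the same length")
    if scores is None:
        s = np.arange(k.size, dtype=float)
    else:
        s = np.asarray(scores, dtype=float)
        if s.shape != k.shape:
            raise ValueError("scores length mismatch")
        if not (np.diff(s) > 0).all():
            raise ValueError("scores must be strictly increasing")
    N = n.sum()
    pbar = k.sum() / N
    sbar = (n * s).sum() / N
    num = (k * (s - sbar)).sum()
    var = pbar * (1.0 - pbar) * (n * (s - sbar) ** 2).sum()
    z = 0.0 if var == 0 else num / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    logger.debug("trend_test z=%.6g p=%.6g", z, p)
    return TestResult(statistic=float(z), p_value=float(min(p, 1.0)))


def pearson_correlation_test(x: Sequence[float], y: Sequence[float]) -> tuple[TestResult, float]:
    """Pearson correlation with a two-sided t-test (df = n - 2).

    Returns ``(TestResult, r)`` where the statistic is the t value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = sps.pearsonr(x, y)
    n = x.size
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    logger.debug("pearson_correlation_test r=%.6g t=%.6g p=%.6g", r, t, p)
    return TestResult(statistic=float(t), p_value=float(p), df=n - 2), float(r)
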