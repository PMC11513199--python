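"""Thin wrappers around the standard tests used in the summaries.

All heavy lifting is scipy/statsmodels; this module just fixes the
conventions used throughout (no continuity correction for chi-square,
explicit errors on degenerate inputs, optional category pooling).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportions_ztest

from .core import ValidationError

__all__ = ["TestResult", "chi_square_test", "prop_test", "t_test", "wilcoxon_test", "pool_tail"]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: Optional[float] = None
    low_expected: bool = False
    method: str = ""


def pool_tail(counts: Sequence[int], from_category: int) -> list[int]:
    """Combine the tail of an ordered count vector into one category.

    Mirrors the reporting convention of pooling sparse high mate/sire
    counts (e.g. "counts combined for three and four mates").
    """
    counts = list(counts)
    if from_category >= len(counts):
        return counts
    return counts[:from_category] + [sum(counts[from_category:])]


def chi_square_test(table: np.ndarray | Sequence[Sequence[int]]) -> TestResult:
    """Pearson chi-square on a contingency table, no continuity correction.

    When any expected cell count is below 1 the result carries a
    ``low_expected`` flag and, for 2x2 tables, Fisher's exact p-value is
    substituted.
    """
    tab = np.asarray(table, dtype=float)
    if tab.ndim != 2 or tab.size == 0:
        raise ValidationError("chi-square needs a 2-D contingency table")
    if tab.sum() == 0:
        raise ValidationError("empty contingency table")
    stat, p, df, expected = sps.chi2_contingency(tab, correction=False)
    low = bool((expected < 1).any())
    if low and tab.shape == (2, 2):
        p = float(sps.fisher_exact(tab)[1])
        return TestResult(float(stat), p, float(df), True, "fisher_exact")
    return TestResult(float(stat), float(p), float(df), low, "chi_square")


def prop_test(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-sample test of proportions (pooled z-test, two-sided)."""
    if min(n1, n2) <= 0:
        raise ValidationError("empty group in proportion test")
    if x1 == x2 and n1 == n2:
        return TestResult(0.0, 1.0, method="prop_ztest")
    stat, p = proportions_ztest([x1, x2], [n1, n2])
    if np.isnan(p):  # both proportions 0 or 1
        return TestResult(0.0, 1.0, method="prop_ztest")
    return TestResult(float(stat), float(p), method="prop_ztest")


def t_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sample t-test (Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("t-test needs >= 2 observations per group")
    if np.var(a) == 0 and np.var(b) == 0 and a.mean() == b.mean():
        return TestResult(0.0, 1.0, method="t_test")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(stat), float(p), method="t_test")


def wilcoxon_test(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney U, normal approximation with ties)."""
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("empty group in rank-sum test")
    stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
    return TestResult(float(stat), float(p), method="wilcoxon_ranksum")
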