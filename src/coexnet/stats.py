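"""Association statistics used throughout the analysis.

Thin, strictly-validated wrappers around the classical tests: Pearson
correlation with a t-based two-sided p, one-way ANOVA, two-sample t
(pooled or Welch), Fisher's exact test and the 2x2 chi-square.  The
heavy lifting is delegated to :mod:`scipy.stats`; this module adds the
input validation, degrees of freedom and a uniform result container.

A Benjamini-Hochberg helper is provided but nothing in this module
applies it implicitly — each test reports its raw p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: float | tuple[float, float] | None = None
    n: int | None = None
    estimate: float | None = None  # r, odds ratio, ... depending on the test

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ContingencyTable2x2:
    """2x2 table of non-negative integer counts.

    Layout::

                     col0   col1
        row0          a      b
        row1          c      d

    e.g. rows = marker high/low, columns = alteration present/absent.
    """

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = field(default=("row0", "row1"))
    col_labels: tuple[str, str] = field(default=("col0", "col1"))

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("empty table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def margins(self) -> tuple[int, int, int, int]:
        """(row0, row1, col0, col1) marginal totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def _as_float_array(x: Sequence[float], name: str, min_n: int) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if arr.size < min_n:
        raise ValueError(f"{name} needs at least {min_n} observations, got {arr.size}")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def pearson_r(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with a two-sided p from the t transform.

    t = r * sqrt((n - 2) / (1 - r^2)) on n - 2 degrees of freedom.
    """
    xa = _as_float_array(x, "x", 3)
    ya = _as_float_array(y, "y", 3)
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = scipy.stats.pearsonr(xa, ya)
    r = float(res.statistic)
    return TestResult(
        statistic=r,
        p_value=float(res.pvalue),
        method="pearson",
        df=xa.size - 2,
        n=xa.size,
        estimate=r,
    )


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA across >= 2 groups; F and its p-value.

    F = (SSB / df_between) / (SSW / df_within); requires some
    within-group variance.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = [_as_float_array(g, f"group {i}", 2) for i, g in enumerate(groups)]
    pooled = np.concatenate(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0:
        raise ValueError("zero within-group variance; F undefined")
    f, p = scipy.stats.f_oneway(*arrays)
    df_between = len(arrays) - 1
    df_within = pooled.size - len(arrays)
    return TestResult(
        statistic=float(f),
        p_value=float(p),
        method="one_way_anova",
        df=(df_between, df_within),
        n=pooled.size,
    )


def two_sample_t(
    x: Sequence[float], y: Sequence[float], welch: bool = False
) -> TestResult:
    """Two-sample t-test, pooled-variance (Student) or Welch."""
    xa = _as_float_array(x, "x", 2)
    ya = _as_float_array(y, "y", 2)
    if not welch:
        pooled_ss = ((xa - xa.mean()) ** 2).sum() + ((ya - ya.mean()) ** 2).sum()
        if pooled_ss == 0 and xa.mean() != ya.mean():
            raise ValueError("zero pooled variance with unequal means; t undefined")
    res = scipy.stats.ttest_ind(xa, ya, equal_var=not welch)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
        method="welch_t" if welch else "student_t",
        df=float(res.df),
        n=xa.size + ya.size,
    )


def fisher_exact_2x2(table: ContingencyTable2x2) -> TestResult:
    """Fisher's exact test, two-sided.

    The two-sided p sums the probabilities of all tables (with the
    observed margins) whose hypergeometric probability is <= the
    observed table's.  The reported estimate is the sample odds ratio
    (a*d)/(b*c), infinite when b*c = 0.
    """
    if 0 in table.margins:
        raise ValueError("Fisher's exact test undefined with a zero margin")
    arr = table.as_array()
    odds, p = scipy.stats.fisher_exact(arr, alternative="two-sided")
    return TestResult(
        statistic=float(odds),
        p_value=float(p),
        method="fisher_exact",
        n=int(arr.sum()),
        estimate=float(odds),
    )


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = False) -> TestResult:
    """Chi-square test of independence on a 2x2 table, 1 df.

    ``yates`` applies the continuity correction.  Expected counts must
    all be positive.
    """
    arr = table.as_array()
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    expected = row * col / arr.sum()
    if (expected == 0).any():
        raise ValueError("zero expected count; chi-square undefined")
    chi2, p, df, _ = scipy.stats.chi2_contingency(arr, correction=yates)
    return TestResult(
        statistic=float(chi2),
        p_value=float(p),
        method="chi_square_yates" if yates else "chi_square",
        df=int(df),
        n=int(arr.sum()),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values (FDR).  Not applied automatically."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def dichotomize_high_low(
    values: Sequence[float], quantile: float = 0.5
) -> np.ndarray:
    """Split a continuous vector into high (True) / low at a quantile.

    The default is a median split; values strictly above the cut are
    "high".  The quantile used should be reported alongside any
    contingency analysis built from this.
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    arr = _as_float_array(values, "values", 2)
    return arr > np.quantile(arr, quantile)
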