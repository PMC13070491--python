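"""Cohort-level statistical comparisons.

Two-sample (Student, pooled-variance) and paired two-sided t-tests,
Pearson correlation, and a dispatcher for declared cohort comparisons of
cell-state composition metrics. Degenerate inputs (zero variance) are
flagged rather than propagated as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "two_sample_ttest",
    "paired_ttest",
    "pearson_correlation",
    "compare_cohorts",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one declared statistical comparison."""

    statistic: float
    df: float
    p_value: float
    group_means: tuple[float, ...]
    n: tuple[int, ...]
    zero_variance: bool = False

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _as_finite_array(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    if not np.isfinite(a).all():
        raise ValueError(f"{name} contains non-finite values")
    return a


def two_sample_ttest(x, y) -> TestResult:
    """Student two-sample t-test (pooled variance), two-sided.

    Both groups with zero variance and equal means yield t = 0, p = 1
    with the zero-variance flag set.
    """
    x = _as_finite_array(x, "x")
    y = _as_finite_array(y, "y")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    df = len(x) + len(y) - 2
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if x.mean() == y.mean():
            return TestResult(0.0, df, 1.0, (x.mean(), y.mean()), (len(x), len(y)), True)
        return TestResult(np.inf, df, 0.0, (x.mean(), y.mean()), (len(x), len(y)), True)
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TestResult(float(t), df, float(p), (x.mean(), y.mean()), (len(x), len(y)))


def paired_ttest(pre, post, subject_ids=None) -> TestResult:
    """Paired two-sided t-test: one-sample t on post - pre differences.

    When ``subject_ids`` are given as (pre_ids, post_ids), they must
    match pairwise; unmatched subjects raise an error listing the ids.
    Constant nonzero differences are flagged (limiting p = 0).
    """
    pre = _as_finite_array(pre, "pre")
    post = _as_finite_array(post, "post")
    if len(pre) != len(post) or len(pre) < 2:
        raise ValueError("pre and post must be equal length >= 2")
    if subject_ids is not None:
        pre_ids, post_ids = subject_ids
        bad = [a for a, b in zip(pre_ids, post_ids) if a != b]
        if bad:
            raise ValueError(f"unmatched subjects: {bad}")
    d = post - pre
    n = len(d)
    if np.var(d, ddof=1) == 0.0:
        if d.mean() == 0.0:
            return TestResult(0.0, n - 1, 1.0, (pre.mean(), post.mean()), (n, n), True)
        return TestResult(
            np.inf if d.mean() > 0 else -np.inf,
            n - 1,
            0.0,
            (pre.mean(), post.mean()),
            (n, n),
            True,
        )
    t, p = sps.ttest_1samp(d, 0.0)
    return TestResult(float(t), n - 1, float(p), (pre.mean(), post.mean()), (n, n))


def pearson_correlation(a, b) -> tuple[float, float, bool]:
    """Sample Pearson r with a two-sided p from the t transform (n-2 df).

    Returns (r, p, degenerate); a zero-variance input yields r = nan
    with the degenerate flag set.
    """
    a = _as_finite_array(a, "a")
    b = _as_finite_array(b, "b")
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("pearson correlation needs paired n >= 3")
    if np.var(a) == 0.0 or np.var(b) == 0.0:
        return float("nan"), float("nan"), True
    r, p = sps.pearsonr(a, b)
    return float(r), float(p), False


def compare_cohorts(
    table: pd.DataFrame,
    metric: str,
    group_a: str,
    group_b: str,
    cohort_col: str = "cohort",
    paired: bool = False,
    genotype_filter: pd.Series | None = None,
) -> TestResult:
    """One declared comparison of a composition metric between two cohorts.

    Dispatches to the pooled-variance two-sample t-test (or the paired
    test when ``paired``; rows are then matched by index order within
    cohort). An optional boolean ``genotype_filter`` (aligned to the
    table index) restricts rows before testing. No multiplicity
    correction is applied: one call is one declared test.
    """
    if metric not in table.columns:
        raise KeyError(f"metric {metric!r} not in table")
    sub = table if genotype_filter is None else table[genotype_filter.reindex(table.index).fillna(False)]
    a = sub.loc[sub[cohort_col] == group_a, metric].to_numpy(dtype=float)
    b = sub.loc[sub[cohort_col] == group_b, metric].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"group sizes after filtering too small: {group_a}={len(a)}, {group_b}={len(b)}"
        )
    if paired:
        return paired_ttest(a, b)
    return two_sample_ttest(a, b)
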