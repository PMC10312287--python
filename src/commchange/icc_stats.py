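"""Intraclass correlation ICC(1,k) for task-type discrimination.

For one edge, arrange the per-session change values in a balanced table of
``n_groups`` task types (targets) by ``k`` sessions (raters).  One-way ANOVA
gives

    ICC(1,k) = (MS_between - MS_within) / MS_between,
    F = MS_between / MS_within,   df1 = n_groups - 1,  df2 = n_groups*(k - 1).

ICC near 1 means between-task differences dominate session noise — the
measure reliably discriminates task type.  Sampling can produce negative
estimates; by default they are floored at 0 with the raw value retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ICCResult", "icc1k", "icc1k_long", "compare_icc_distributions"]


@dataclass(frozen=True)
class ICCResult:
    icc: float  # floored at 0 unless floor_negative=False
    icc_raw: float  # unfloored estimate
    f_stat: float
    df1: int
    df2: int
    p_value: float


def icc1k(table: np.ndarray, floor_negative: bool = True) -> ICCResult:
    """ICC(1,k) from a balanced groups-by-raters table.

    Rows are groups (task types), columns raters (sessions).  Requires at
    least 2 groups and 2 raters.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2:
        raise ValueError("table must be 2-dimensional (groups x raters)")
    n_groups, k = arr.shape
    if n_groups < 2 or k < 2:
        raise ValueError("need at least 2 groups and 2 raters per group")
    if np.any(np.isnan(arr)):
        raise ValueError("table is unbalanced (contains missing values)")

    grand = arr.mean()
    group_means = arr.mean(axis=1)
    ss_between = k * ((group_means - grand) ** 2).sum()
    ss_within = ((arr - group_means[:, None]) ** 2).sum()
    df1 = n_groups - 1
    df2 = n_groups * (k - 1)
    ms_between = ss_between / df1
    ms_within = ss_within / df2

    if ms_within == 0:
        icc_raw = 1.0 if ms_between > 0 else 0.0
        f = np.inf if ms_between > 0 else np.nan
        p = 0.0 if ms_between > 0 else np.nan
    else:
        icc_raw = (ms_between - ms_within) / ms_between if ms_between > 0 else -np.inf
        f = ms_between / ms_within
        p = float(stats.f.sf(f, df1, df2))
    icc = max(icc_raw, 0.0) if floor_negative else icc_raw
    return ICCResult(
        icc=float(icc), icc_raw=float(icc_raw), f_stat=float(f),
        df1=df1, df2=df2, p_value=p,
    )


def icc1k_long(
    df: pd.DataFrame,
    group_col: str = "condition",
    rater_col: str = "session",
    value_col: str = "value",
    floor_negative: bool = True,
) -> ICCResult:
    """ICC(1,k) from a long-format table with group/rater/value columns."""
    wide = df.pivot_table(index=group_col, columns=rater_col, values=value_col)
    if wide.isna().any().any():
        raise ValueError("unbalanced design: every group needs every rater")
    return icc1k(wide.to_numpy(), floor_negative=floor_negative)


def compare_icc_distributions(icc_a: np.ndarray, icc_b: np.ndarray) -> tuple[float, float]:
    """Paired z-comparison of two per-edge ICC distributions (descriptive).

    Wilcoxon signed-rank test with normal approximation on the paired
    differences; returns (z, two-sided p).  The sign of z follows the sign
    of the mean difference a - b.
    """
    a = np.asarray(icc_a, dtype=float)
    b = np.asarray(icc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    res = stats.wilcoxon(a, b, zero_method="wilcox", method="approx")
    z = float(stats.norm.isf(res.pvalue / 2.0))
    if np.mean(a - b) < 0:
        z = -z
    return z, float(res.pvalue)
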