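"""Group summaries and significance conventions.

Results are expressed as mean ± SEM; treated groups are compared to the
untreated group with a two-tailed unpaired t test (Student pooled-variance
by default, Welch optional) and annotated with the star tiers
``* p ≤ 0.05, ** p ≤ 0.01, *** p ≤ 0.001, **** p ≤ 0.0001``.
Technical replicates are averaged within their biological replicate before
testing by default (``unit="biological"``); set ``unit="technical"`` to
treat every spectrum as an independent observation.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "mean_sem",
    "two_sample_t",
    "significance_tier",
    "group_summary",
]

TIERS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def mean_sem(values: Sequence[float]) -> tuple[float, float]:
    """Sample mean and standard error of the mean (n−1 denominator sd)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("SEM undefined for fewer than two values")
    return float(x.mean()), float(x.std(ddof=1) / math.sqrt(x.size))


def two_sample_t(a: Sequence[float], b: Sequence[float],
                 variant: str = "student") -> tuple[float, float, float]:
    """Two-tailed unpaired t test; returns (t, df, p).

    ``student`` pools variances (df = n₁+n₂−2); ``welch`` uses the
    Welch–Satterthwaite degrees of freedom.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two values")
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        warnings.warn("zero variance with unequal means: p -> 0",
                      RuntimeWarning)
        t = -math.inf if x.mean() < y.mean() else math.inf
        return t, float(x.size + y.size - 2), 0.0
    res = sps.ttest_ind(x, y, equal_var=(variant == "student"))
    return float(res.statistic), float(res.df), float(res.pvalue)


def significance_tier(p: float) -> str:
    """Star label for a p value; boundaries closed (≤) per convention."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p value outside [0, 1]: {p}")
    for threshold, label in TIERS:
        if p <= threshold:
            return label
    return "ns"


def _aggregate(df: pd.DataFrame, value: str, unit: str) -> pd.DataFrame:
    if unit == "technical":
        return df
    if unit != "biological":
        raise ValueError(f"unknown unit {unit!r}")
    keys = [k for k in ("cell_line", "dose", "bio_rep") if k in df.columns]
    return df.groupby(keys, sort=False, as_index=False)[value].mean()


def group_summary(
    table: pd.DataFrame,
    value: str = "percent",
    group: str = "dose",
    reference: float = 0.0,
    variant: str = "student",
    unit: str = "biological",
) -> pd.DataFrame:
    """Per-group mean ± SEM with t test versus the reference group.

    ``unit="biological"`` (default) first averages technical replicates
    within each biological replicate; ``unit="technical"`` uses every row.
    The reference group (untreated, by default ``dose == 0``) gets no test.
    """
    if value not in table.columns:
        raise ValueError(f"no column {value!r} in table")
    df = _aggregate(table, value, unit)
    if reference not in set(df[group]):
        raise ValueError(f"reference group {group}={reference} missing")
    ref_values = df.loc[df[group] == reference, value].to_numpy()
    rows = []
    for g, sub in df.groupby(group, sort=True):
        vals = sub[value].to_numpy()
        mean, sem = mean_sem(vals) if vals.size >= 2 else (float(vals.mean()),
                                                           np.nan)
        row = {group: g, "n": vals.size, "mean": mean, "sem": sem,
               "t": np.nan, "p": np.nan, "tier": ""}
        if g != reference:
            t, dof, p = two_sample_t(vals, ref_values, variant=variant)
            row.update(t=t, p=p, tier=significance_tier(p))
        rows.append(row)
    return pd.DataFrame(rows)
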