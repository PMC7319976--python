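"""Cohort statistics: replicate aggregation, t-tests, percent change.

The study design is hierarchical: several images (technical replicates) per
mouse, several mice (biological replicates) per age group.  All technical
replicates are averaged to one value per mouse before testing, and the two
groups are compared with a two-tailed two-sample t-test (Student pooled
variance by default; Welch optional).  No multiple-testing correction is
applied across metrics — each metric is tested independently, which is a
documented caveat of the design, not an oversight of this implementation.

Percent changes are reported as reductions relative to the young group,
rounded half-away-from-zero to integer percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class MouseSummary:
    mouse_id: str
    group: str
    metric: str
    value: float


@dataclass
class GroupComparison:
    metric: str
    mean_young: float
    sd_young: float
    n_young: int
    mean_old: float
    sd_old: float
    n_old: int
    percent_change: float  # positive = reduction with age
    t_stat: float
    df: float
    p_two_tailed: float
    variant: str = "pooled"

    @property
    def percent_change_rounded(self) -> int:
        return round_percent(self.percent_change)


def aggregate_mouse(field_values, metric: str = "", group_of=None) -> list:
    """Unweighted mean per mouse over its technical replicates.

    ``field_values`` is an iterable of ``(mouse_id, value)`` pairs;
    ``group_of`` optionally maps mouse_id → group label.
    """
    pairs = list(field_values)
    if not pairs:
        raise StatsError("no field values")
    acc: dict = {}
    for mouse_id, value in pairs:
        if not np.isfinite(value):
            raise StatsError(f"non-finite value for mouse {mouse_id!r}")
        acc.setdefault(mouse_id, []).append(float(value))
    out = []
    for mouse_id in acc:  # insertion order: first appearance
        group = group_of(mouse_id) if callable(group_of) else (
            group_of.get(mouse_id, "") if group_of else ""
        )
        out.append(MouseSummary(mouse_id, group, metric, float(np.mean(acc[mouse_id]))))
    return out


def aggregate_frame(df: pd.DataFrame, value: str, mouse: str = "mouse_id",
                    group: str = "group") -> pd.DataFrame:
    """DataFrame front-end: one row per mouse with the mean of ``value``."""
    return df.groupby([group, mouse], as_index=False)[value].mean()


def _comparison_from_stats(my, sy, ny, mo, so, no, variant, metric):
    if ny < 2 or no < 2:
        raise StatsError("each group needs at least 2 mice")
    if variant not in ("pooled", "welch"):
        raise StatsError(f"unknown t-test variant {variant!r}")
    if sy == 0 and so == 0:
        if my == mo:
            t, df, p = 0.0, float(ny + no - 2), 1.0
        else:
            t, df, p = math.inf if my > mo else -math.inf, float(ny + no - 2), 0.0
    else:
        res = sps.ttest_ind_from_stats(
            my, sy, ny, mo, so, no, equal_var=(variant == "pooled")
        )
        t, p = float(res.statistic), float(res.pvalue)
        if variant == "pooled":
            df = float(ny + no - 2)
        else:
            vy, vo = sy**2 / ny, so**2 / no
            df = (vy + vo) ** 2 / (vy**2 / (ny - 1) + vo**2 / (no - 1))
    pct = percent_change(my, mo) if my != 0 else float("nan")
    return GroupComparison(metric, my, sy, ny, mo, so, no, pct, t, df, p, variant)


def two_tailed_t(young, old, variant: str = "pooled", metric: str = "") -> GroupComparison:
    """Two-sample two-tailed t-test on per-mouse values."""
    y = np.asarray(list(young), dtype=float)
    o = np.asarray(list(old), dtype=float)
    if len(y) < 2 or len(o) < 2:
        raise StatsError("each group needs at least 2 mice")
    return _comparison_from_stats(
        float(y.mean()), float(y.std(ddof=1)), len(y),
        float(o.mean()), float(o.std(ddof=1)), len(o),
        variant, metric,
    )


def two_tailed_t_from_stats(
    mean_young, sd_young, n_young, mean_old, sd_old, n_old,
    variant: str = "pooled", metric: str = "",
) -> GroupComparison:
    """Summary-statistic entry point (printed mean, SD, n per group)."""
    return _comparison_from_stats(
        float(mean_young), float(sd_young), int(n_young),
        float(mean_old), float(sd_old), int(n_old), variant, metric,
    )


def percent_change(mean_young: float, mean_old: float) -> float:
    """Reduction with age as a percentage of the young mean.

    Positive when the old group is lower.  Use :func:`round_percent` for
    the integer value quoted in prose.
    """
    if mean_young == 0:
        raise StatsError("zero baseline")
    return 100.0 * (mean_young - mean_old) / mean_young


def round_percent(pct: float) -> int:
    """Round half away from zero to integer percent (prose convention)."""
    return int(math.floor(abs(pct) + 0.5)) * (1 if pct >= 0 else -1)


def compare_groups(
    df: pd.DataFrame,
    metrics=None,
    variant: str = "pooled",
    value: str = "value",
    metric_col: str = "metric",
    mouse: str = "mouse_id",
    group: str = "group",
    young: str = "young",
    old: str = "old",
) -> pd.DataFrame:
    """Aggregate to mouse means and test every metric in a long DataFrame."""
    rows = []
    for m in metrics if metrics is not None else df[metric_col].unique():
        sub = df[df[metric_col] == m]
        mm = aggregate_frame(sub, value, mouse=mouse, group=group)
        cmp_ = two_tailed_t(
            mm.loc[mm[group] == young, value],
            mm.loc[mm[group] == old, value],
            variant=variant,
            metric=m,
        )
        rows.append(
            dict(
                metric=m,
                mean_young=cmp_.mean_young, sd_young=cmp_.sd_young, n_young=cmp_.n_young,
                mean_old=cmp_.mean_old, sd_old=cmp_.sd_old, n_old=cmp_.n_old,
                percent_change=cmp_.percent_change,
                percent_change_rounded=cmp_.percent_change_rounded,
                t_stat=cmp_.t_stat, df=cmp_.df, p_two_tailed=cmp_.p_two_tailed,
                variant=variant,
            )
        )
    return pd.DataFrame(rows)


def simulate_power(
    young_params,
    old_params,
    n_mice: int = 4,
    fields_per_mouse: int = 3,
    reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    variant: str = "pooled",
) -> float:
    """Monte-Carlo rejection rate of the full aggregate→t pipeline.

    ``young_params``/``old_params`` are ``(group_mean, between_mouse_sd,
    within_mouse_sd)``.  With equal group parameters this estimates the
    type-I error (nominally ``alpha``); with unequal means it estimates
    power.  Reproducible for a fixed seed.
    """
    if reps < 100:
        raise StatsError("reps must be >= 100")
    if n_mice < 2 or fields_per_mouse < 1:
        raise StatsError("invalid cohort size")
    my, by, wy = (float(v) for v in young_params)
    mo, bo, wo = (float(v) for v in old_params)
    if min(by, wy, bo, wo) < 0:
        raise StatsError("SDs must be >= 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    hits = 0
    for _ in range(reps):
        ym = rng.normal(my, by, n_mice)
        om = rng.normal(mo, bo, n_mice)
        yv = rng.normal(ym[:, None], wy, (n_mice, fields_per_mouse)).mean(axis=1)
        ov = rng.normal(om[:, None], wo, (n_mice, fields_per_mouse)).mean(axis=1)
        if two_tailed_t(yv, ov, variant=variant).p_two_tailed < alpha:
            hits += 1
    return hits / reps
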