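"""Furrow-canal (FC) fluorescence aggregation.

Per-furrow mean intensities measured in fixed, stained embryos are aggregated
hierarchically: furrows are averaged within each embryo first, then embryo
means are averaged per developmental stage and channel, with the SEM taken
across embryos. Embryos therefore carry equal weight regardless of how many
furrows were scored in each. Stage times are caller-provided minutes relative
to mitosis 13 (staging by morphology happens upstream).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MEASUREMENT_COLUMNS",
    "GroupComparison",
    "aggregate_profile",
    "fold_change",
    "compare_groups",
]

MEASUREMENT_COLUMNS = ("embryo", "stage_min", "furrow", "channel", "intensity")


def _validate(measurements: pd.DataFrame) -> pd.DataFrame:
    missing = set(MEASUREMENT_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")
    if measurements.empty:
        raise ValueError("measurement table is empty")
    if (measurements["intensity"].astype(float) < 0).any():
        raise ValueError("intensities must be >= 0")
    if not np.isfinite(measurements["stage_min"].astype(float)).all():
        raise ValueError("stage times must be finite")
    return measurements


def aggregate_profile(measurements: pd.DataFrame) -> pd.DataFrame:
    """Two-level mean ± SEM profile per (stage_min, channel).

    Returns a frame indexed by (stage_min, channel) with columns ``mean``,
    ``sem`` (sd of embryo means / sqrt(n), ddof=1; 0 for a single embryo,
    flagged via ``n_embryos``) and ``n_embryos``.
    """
    m = _validate(measurements)
    embryo_means = (
        m.groupby(["stage_min", "channel", "embryo"], sort=True)["intensity"]
        .mean()
        .rename("embryo_mean")
        .reset_index()
    )
    rows = []
    for (stage, channel), grp in embryo_means.groupby(["stage_min", "channel"], sort=True):
        vals = grp["embryo_mean"].to_numpy(dtype=float)
        n = vals.size
        if n == 1:
            warnings.warn(
                f"single embryo at stage {stage} ({channel}); SEM undefined, reported as 0",
                stacklevel=2,
            )
            sem = 0.0
        else:
            sem = float(np.std(vals, ddof=1) / math.sqrt(n))
        rows.append(
            {
                "stage_min": stage,
                "channel": channel,
                "mean": float(vals.mean()),
                "sem": sem,
                "n_embryos": n,
            }
        )
    return pd.DataFrame(rows).set_index(["stage_min", "channel"])


def fold_change(profile: pd.DataFrame, t0: float, t1: float, channel: str) -> float:
    """Grand-mean ratio between two stages of one channel: mean(t1)/mean(t0)."""
    for t in (t0, t1):
        if (t, channel) not in profile.index:
            raise KeyError(f"stage {t} ({channel}) not present in profile")
    baseline = profile.at[(t0, channel), "mean"]
    if baseline <= 0:
        raise ZeroDivisionError(f"baseline mean at stage {t0} is {baseline}; ratio undefined")
    return float(profile.at[(t1, channel), "mean"] / baseline)


@dataclass(frozen=True)
class GroupComparison:
    t_statistic: float
    p_value: float
    degrees_of_freedom: float
    equal_variance: bool


def compare_groups(
    a: Sequence[float], b: Sequence[float], equal_var: bool = True
) -> GroupComparison:
    """Two-sample Student t test (Welch with ``equal_var=False``).

    Degenerate input with zero variance in both groups and equal means is
    reported as t = 0, p = 1 by convention.
    """
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x) == 0 and np.var(y) == 0 and x.mean() == y.mean():
        df = x.size + y.size - 2 if equal_var else float(x.size + y.size - 2)
        return GroupComparison(0.0, 1.0, float(df), equal_var)
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return GroupComparison(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        degrees_of_freedom=float(res.df),
        equal_variance=equal_var,
    )
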