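"""In vivo tumor-growth quantification.

Tumor volume from caliper axes (``TV = L * S^2 / 2`` in mm^3), the
treated-over-control growth statistic ΔT/C (%), last-observation-carried-
forward (LOCF) imputation for missing follow-up, and the pooled-variance
unpaired t test used for two-group readouts.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def tumor_volume(long_axis, short_axis):
    """Tumor volume ``L * S^2 / 2`` (mm^3); axes are swapped (with a log
    note) wherever the short axis exceeds the long axis."""
    L = np.asarray(long_axis, dtype=float)
    S = np.asarray(short_axis, dtype=float)
    if (L <= 0).any() or (S <= 0).any():
        raise ValueError("tumor axes must be positive")
    swapped = S > L
    if swapped.any():
        logger.info("swapped %d axis pair(s) where short > long", int(swapped.sum()))
        L, S = np.where(swapped, S, L), np.where(swapped, L, S)
    volume = L * S**2 / 2.0
    return float(volume) if volume.ndim == 0 else volume


def series_volumes(series: pd.DataFrame) -> pd.DataFrame:
    """Tidy (mouse_id, group, day, long_axis, short_axis) -> add a volume
    column; returns a copy sorted by mouse then day."""
    out = series.sort_values(["mouse_id", "day"]).reset_index(drop=True).copy()
    out["volume"] = tumor_volume(out["long_axis"].to_numpy(), out["short_axis"].to_numpy())
    return out


def locf_impute(volumes: pd.DataFrame, schedule: Sequence[int]) -> pd.DataFrame:
    """Fill missing scheduled measurements by carrying the last observed
    volume forward.

    ``volumes`` is a mice x days table (rows = mouse ids, columns = days);
    ``schedule`` lists the scheduled measurement days.  The first scheduled
    day must be observed for every mouse.  Idempotent.
    """
    schedule = sorted(schedule)
    table = volumes.reindex(columns=schedule)
    first = table[schedule[0]]
    if first.isna().any():
        mouse = first.index[first.isna()][0]
        raise ValueError(f"mouse {mouse!r} is missing the first scheduled observation")
    return table.ffill(axis=1)


def volume_table(series: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy growth series into a mice x days volume table."""
    with_vol = series_volumes(series)
    return with_vol.pivot(index="mouse_id", columns="day", values="volume")


def delta_t_over_c(
    treated: pd.DataFrame,
    control: pd.DataFrame,
    day: int,
    baseline_day: "int | None" = None,
) -> float:
    """ΔT/C (%) — treated over control mean tumor-volume change from baseline.

    Inputs are mice x days volume tables (post-LOCF).  ``baseline_day``
    defaults to each table's earliest day.  ΔC = 0 is an error.
    """
    def delta(table: pd.DataFrame) -> float:
        base = baseline_day if baseline_day is not None else min(table.columns)
        for col in (base, day):
            if col not in table.columns:
                raise ValueError(f"day {col} not present in volume table")
        return float(table[day].mean() - table[base].mean())

    dt, dc = delta(treated), delta(control)
    if dc == 0:
        raise ValueError("control group volume change is zero; ΔT/C undefined")
    return 100.0 * dt / dc


def unpaired_t(group_a, group_b) -> "tuple[float, float]":
    """Two-sample pooled-variance (Student) t test, two-sided.

    Returns ``(t, p)``; zero pooled variance is an error.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if pooled_ss == 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
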