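"""Maximum specific growth-rate estimation from plate-reader OD600 curves.

The estimator follows the standard sliding-window protocol for microbial
growth curves: background-correct the OD series, keep points above a
detection threshold, fit ordinary least squares to ln(OD) against time in
every run of `window` consecutive retained points, and report the largest
slope (converted to per-hour) as mu_max.  Replicate estimates are averaged
per genotype and sugar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthCurve",
    "GrowthRateEstimate",
    "background_correct",
    "max_growth_rate",
    "aggregate_replicates",
]


@dataclass
class GrowthCurve:
    """One well's OD600 time series.

    time_min is a strictly increasing grid in minutes (nominally 10-min
    spacing); ``blank_od600`` is the background reference.  When the blank
    is None it defaults to the minimum of the first three readings.
    """

    time_min: np.ndarray
    od600: np.ndarray
    blank_od600: float | None = None
    corrected: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        if self.time_min.shape != self.od600.shape:
            raise ValueError("time_min and od600 must have equal length")
        if len(self.time_min) and np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time_min must be strictly increasing")
        # NaN marks a masked (background-subtracted, non-positive) reading
        if np.any(np.isinf(self.od600)):
            raise ValueError("od600 must not contain infinities")


@dataclass
class GrowthRateEstimate:
    """mu_max (1/h) with provenance of the winning regression window."""

    mu_max: float | None
    window_start_index: int
    n_windows_used: int
    status: str  # "ok" | "insufficient_points"


def background_correct(curve: GrowthCurve) -> GrowthCurve:
    """Subtract the blank; non-positive values are masked (set to NaN).

    A NaN-masked point never enters a regression window downstream.
    """
    blank = curve.blank_od600
    if blank is None:
        blank = float(np.min(curve.od600[:3]))
    od = curve.od600 - blank
    od = np.where(od > 0, od, np.nan)
    return GrowthCurve(curve.time_min, od, blank_od600=0.0, corrected=True)


def max_growth_rate(
    curve: GrowthCurve,
    window: int = 5,
    min_od: float = 0.16,
) -> GrowthRateEstimate:
    """Local log-linear regression estimate of the maximum growth rate.

    Points with background-corrected OD600 > ``min_od`` are retained; for
    every run of ``window`` points that are *consecutive in the original
    sampling grid* an OLS line is fitted to ln(OD) vs time, and the
    largest slope (x60, per hour) is reported.  Windows spanning gaps in
    the retained index sequence are skipped.  Ties go to the earliest
    window.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    od = curve.od600
    t_h = curve.time_min / 60.0
    eligible = np.flatnonzero(np.isfinite(od) & (od > min_od))
    best_slope = -np.inf
    best_start = -1
    n_windows = 0
    for i in range(len(eligible) - window + 1):
        idx = eligible[i : i + window]
        if idx[-1] - idx[0] != window - 1:  # gap in the retained sequence
            continue
        n_windows += 1
        x = t_h[idx]
        y = np.log(od[idx])
        slope = np.polyfit(x, y, 1)[0]
        if slope > best_slope + 0.0:  # strict: earliest window wins ties
            best_slope = slope
            best_start = int(idx[0])
    if n_windows == 0:
        return GrowthRateEstimate(None, -1, 0, "insufficient_points")
    return GrowthRateEstimate(float(best_slope), best_start, n_windows, "ok")


def aggregate_replicates(estimates: list[GrowthRateEstimate]) -> tuple[float | None, int]:
    """Arithmetic mean of mu_max over replicates with status "ok".

    Returns ``(mean, n_contributing)``; ``(None, 0)`` when no replicate
    produced an estimate.
    """
    ok = [e.mu_max for e in estimates if e.status == "ok" and e.mu_max is not None]
    if not ok:
        return None, 0
    return float(np.mean(ok)), len(ok)


def rates_from_table(
    df: pd.DataFrame,
    window: int = 5,
    min_od: float = 0.16,
    blank: float | None = None,
) -> pd.DataFrame:
    """Estimate per-genotype, per-sugar mean mu_max from a long table.

    Expects columns ``genotype, sugar, replicate, time_min, od600`` (extra
    columns such as plate/well are carried along if constant per group).
    Returns one row per (genotype, sugar) with ``mu_max`` and ``n_replicates``.
    """
    required = {"genotype", "sugar", "replicate", "time_min", "od600"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"growth table is missing columns: {sorted(missing)}")
    rows = []
    for (genotype, sugar), grp in df.groupby(["genotype", "sugar"], sort=True):
        estimates = []
        for _, rep in grp.groupby("replicate", sort=True):
            rep = rep.sort_values("time_min")
            curve = GrowthCurve(
                rep["time_min"].to_numpy(), rep["od600"].to_numpy(), blank_od600=blank
            )
            estimates.append(max_growth_rate(background_correct(curve), window, min_od))
        mean, n = aggregate_replicates(estimates)
        rows.append(
            {"genotype": genotype, "sugar": sugar, "mu_max": mean, "n_replicates": n}
        )
    return pd.DataFrame(rows)
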