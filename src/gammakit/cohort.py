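"""Baseline normalization, cohort aggregation and endpoint evaluation.

Oscillation metrics are highly variable across slices, so every metric is
normalized within-slice to the mean of a 10-min baseline period (the 10 min
preceding drug application or agonist wash-out, or the matching clock time in
control arms) and expressed in percent. Normalized metrics are summarized as
mean ± SEM across slices; absolute peak powers are log-normally distributed
across slices and are summarized as geometric mean with a back-transformed
t confidence interval instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .spectral import METRIC_NAMES, TimeCourse

__all__ = [
    "GroupSummary",
    "PowerSummary",
    "normalize_to_baseline",
    "aggregate_group",
    "absolute_power_summary",
    "evaluate_endpoint",
]


@dataclass
class GroupSummary:
    """Per-timepoint mean ± SEM for each metric over a group of slices."""

    table: pd.DataFrame  # columns: window_start_min, metric, mean, sem, n

    def at(self, window_start_min: float, metric: str) -> tuple[float, float, int]:
        t = self.table
        row = t[
            (np.isclose(t.window_start_min, window_start_min)) & (t.metric == metric)
        ]
        if row.empty:
            raise KeyError(f"no summary at {window_start_min} min for {metric}")
        r = row.iloc[0]
        return float(r["mean"]), float(r["sem"]), int(r["n"])


@dataclass
class PowerSummary:
    """Geometric mean and CI of absolute peak powers (µV²)."""

    geometric_mean: float
    ci_low: float
    ci_high: float
    level: float
    n: int


def _baseline_windows(tc: TimeCourse, baseline: tuple[float, float]) -> np.ndarray:
    starts = np.asarray(tc.window_start_min)
    lo, hi = baseline
    return (starts >= lo - 1e-9) & (starts + tc.window_length_min <= hi + 1e-9)


def normalize_to_baseline(
    tc: TimeCourse, baseline: tuple[float, float]
) -> TimeCourse:
    """Express every metric as percent of its mean over the baseline interval.

    Only windows lying fully inside ``baseline`` and flagged valid enter the
    baseline mean. Raises if the time course is already normalized or if the
    baseline contains no valid window.
    """
    if tc.normalization != "absolute":
        raise ValueError("time course is already normalized")
    in_base = _baseline_windows(tc, baseline)
    usable = in_base & np.asarray(tc.valid)
    if not usable.any():
        raise ValueError(f"no valid analysis window inside baseline {baseline}")
    new = {}
    for name in METRIC_NAMES:
        vals = np.asarray(tc.metric(name), dtype=float)
        ref = np.nanmean(vals[usable])
        new[name] = vals / ref * 100.0
    return tc.copy_with(
        normalization="percent_of_baseline",
        baseline_interval=(float(baseline[0]), float(baseline[1])),
        **new,
    )


def aggregate_group(tcs: list[TimeCourse]) -> GroupSummary:
    """Per-timepoint mean and SEM over slices (valid windows only).

    All time courses must share the same window grid. SEM is 0 by convention
    when a timepoint has a single contributing slice.
    """
    if not tcs:
        raise ValueError("empty group")
    grid = np.asarray(tcs[0].window_start_min)
    for tc in tcs[1:]:
        if len(tc) != len(tcs[0]) or not np.allclose(tc.window_start_min, grid):
            raise ValueError("time courses are not on a common window grid")
    rows = []
    for name in METRIC_NAMES:
        stack = np.vstack([np.asarray(tc.metric(name), dtype=float) for tc in tcs])
        valid = np.vstack([np.asarray(tc.valid) for tc in tcs]) & np.isfinite(stack)
        for j, t in enumerate(grid):
            col = stack[valid[:, j], j]
            n = col.size
            if n == 0:
                mean, sem = np.nan, np.nan
            elif n == 1:
                mean, sem = float(col[0]), 0.0
            else:
                mean = float(col.mean())
                sem = float(col.std(ddof=1) / np.sqrt(n))
            rows.append(
                {"window_start_min": float(t), "metric": name, "mean": mean, "sem": sem, "n": n}
            )
    return GroupSummary(pd.DataFrame(rows))


def absolute_power_summary(values, level: float = 0.95) -> PowerSummary:
    """Geometric mean with back-transformed t confidence interval.

    Appropriate for log-normally distributed absolute peak powers: the CI is a
    t interval on the log values, exponentiated back to µV².
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    if np.any(v <= 0):
        raise ValueError("absolute powers must be positive")
    logs = np.log(v)
    m = logs.mean()
    s = logs.std(ddof=1)
    half = sps.t.ppf(0.5 + level / 2.0, v.size - 1) * s / np.sqrt(v.size)
    return PowerSummary(
        geometric_mean=float(np.exp(m)),
        ci_low=float(np.exp(m - half)),
        ci_high=float(np.exp(m + half)),
        level=level,
        n=int(v.size),
    )


def evaluate_endpoint(
    tc: TimeCourse, at: float, average_over: float | None = None
) -> dict[str, float]:
    """Per-metric mean over the windows ending at minute ``at``.

    ``average_over`` defaults to one window step, i.e. the single analysis
    window ``[at - step, at)``. Windows must exist inside the requested
    interval; invalid windows are excluded (NaN is returned if none in the
    interval are valid).
    """
    starts = np.asarray(tc.window_start_min)
    if average_over is None:
        average_over = tc.window_length_min
    lo = at - average_over
    sel = (starts >= lo - 1e-9) & (starts < at - 1e-9)
    covered = starts + tc.window_length_min
    if not sel.any() or at > covered.max() + 1e-9:
        raise ValueError(f"endpoint interval [{lo}, {at}] min not covered by recording")
    out = {}
    valid = np.asarray(tc.valid) & sel
    for name in METRIC_NAMES:
        vals = np.asarray(tc.metric(name), dtype=float)[valid]
        vals = vals[np.isfinite(vals)]
        out[name] = float(vals.mean()) if vals.size else float("nan")
    return out
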