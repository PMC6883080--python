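"""Swelling statistics: normalized area traces, per-cycle swelling, and
cell-size comparisons.

The central quantity is the per-cycle swelling percentage: within each
oxygen cycle, the peak normalized area reached during the 0%-O2 phase (plus
a configurable lag accommodating the sub-hour response latency) relative to
the trough of the preceding shrink interval.  Summary error bars follow the
conventions of the source experiment: SD across cycles for the per-cycle
summary, SE across spheroids or pooled cells for time courses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .schedule import OxygenSchedule
from .segmentation import CellSegmentation

_TOL = 1e-9


@dataclass
class AreaTrace:
    """Normalized projected-area time series: 100% at the first timestamp."""

    timestamps_min: np.ndarray
    values_pct: np.ndarray
    track_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps_min = np.asarray(self.timestamps_min, dtype=float)
        self.values_pct = np.asarray(self.values_pct, dtype=float)
        if self.timestamps_min.shape != self.values_pct.shape:
            raise ValueError("timestamps and values must have equal length")
        if len(self.values_pct) == 0:
            raise ValueError("empty trace")
        if not np.all(np.isfinite(self.values_pct)) or np.any(self.values_pct <= 0):
            raise ValueError("trace values must be finite and positive")
        if abs(self.values_pct[0] - 100.0) > 1e-6:
            raise ValueError(
                f"normalized trace must start at 100%, got {self.values_pct[0]}"
            )


def normalize_trace(
    raw_areas: Sequence[float],
    timestamps_min: Sequence[float],
    track_id: str = "",
) -> AreaTrace:
    """Areas as percent of the area at the first timestamp."""
    areas = np.asarray(raw_areas, dtype=float)
    if len(areas) == 0:
        raise ValueError("empty area trace")
    if not np.isfinite(areas[0]) or areas[0] <= 0:
        raise ValueError(f"initial area must be finite and > 0, got {areas[0]}")
    return AreaTrace(
        timestamps_min=np.asarray(timestamps_min, dtype=float),
        values_pct=100.0 * areas / areas[0],
        track_id=track_id,
    )


@dataclass
class MeanTrace:
    """Pointwise cohort mean with standard error (SD/sqrt(N))."""

    timestamps_min: np.ndarray
    mean_pct: np.ndarray
    se_pct: np.ndarray
    n: int

    def as_trace(self) -> AreaTrace:
        # renormalize: interpolation can move the first point off 100 slightly
        return normalize_trace(self.mean_pct, self.timestamps_min, track_id="cohort-mean")


def cohort_mean_se(
    traces: Sequence[AreaTrace], allow_single: bool = False
) -> MeanTrace:
    """Pointwise mean and SE over traces, resampled to a common time grid.

    The grid is the first trace's timestamps restricted to the overlap of
    all traces; other traces are linearly interpolated (never extrapolated).
    """
    traces = list(traces)
    if len(traces) == 0:
        raise ValueError("no traces")
    if len(traces) < 2 and not allow_single:
        raise ValueError("SE undefined for a single trace (pass allow_single=True)")
    t_lo = max(tr.timestamps_min[0] for tr in traces)
    t_hi = min(tr.timestamps_min[-1] for tr in traces)
    if t_hi < t_lo:
        raise ValueError("traces do not overlap in time")
    grid = traces[0].timestamps_min
    grid = grid[(grid >= t_lo - _TOL) & (grid <= t_hi + _TOL)]
    if len(grid) == 0:
        raise ValueError("no common timepoints after restriction to overlap")
    vals = np.vstack(
        [np.interp(grid, tr.timestamps_min, tr.values_pct) for tr in traces]
    )
    mean = vals.mean(axis=0)
    if len(traces) > 1:
        se = vals.std(axis=0, ddof=1) / np.sqrt(len(traces))
    else:
        se = np.zeros_like(mean)
    return MeanTrace(timestamps_min=grid, mean_pct=mean, se_pct=se, n=len(traces))


@dataclass
class SwellingSummary:
    """Per-cycle swelling percentages with mean and SD across cycles."""

    per_cycle_pct: np.ndarray
    mean_pct: float
    sd_pct: float
    n_cycles: int
    n_spheroids: int

    def __post_init__(self) -> None:
        self.per_cycle_pct = np.asarray(self.per_cycle_pct, dtype=float)
        if len(self.per_cycle_pct) != self.n_cycles:
            raise ValueError("per_cycle_pct length must equal n_cycles")
        if self.sd_pct < 0:
            raise ValueError("SD must be >= 0")


def per_cycle_swelling(
    trace: AreaTrace,
    schedule: OxygenSchedule,
    n_cycles: int = 3,
    peak_lag_min: float = 60.0,
    peak_window: str = "zero_phase_plus_lag",
    t0_min: float = 0.0,
    n_spheroids: int = 1,
) -> SwellingSummary:
    """Per-cycle swelling of a (cohort-mean) normalized area trace.

    For cycle i, swelling_i = 100 * (peak - trough) / trough where the peak
    is the max area in the cycle's most-hypoxic phase extended by
    ``peak_lag_min`` (or the whole cycle for ``peak_window='full_cycle'``)
    and the trough is the min area in the preceding shrink interval (from
    the end of the previous cycle's peak window; for the first cycle, from
    the start of the trace).

    ``t0_min`` is the trace time at which the schedule starts; the statistic
    is invariant under shifting trace timestamps and ``t0_min`` together.
    """
    if peak_window not in ("zero_phase_plus_lag", "full_cycle"):
        raise ValueError(f"unknown peak_window {peak_window!r}")
    t = trace.timestamps_min - t0_min
    v = trace.values_pct
    cycle = schedule.cycle_min
    zero_level = min(schedule.o2_levels())
    # offset of the first most-hypoxic phase within one cycle
    first_cycle_windows = [
        (a, b)
        for a, b, o2 in schedule.intervals()
        if abs(o2 - zero_level) <= _TOL and b <= cycle + _TOL
    ]
    if not first_cycle_windows:
        raise ValueError("schedule has no hypoxic phase within one cycle")
    a0, b0 = first_cycle_windows[0]

    needed = (n_cycles - 1) * cycle + b0
    available = int(np.floor((t[-1] - a0 + _TOL) / cycle)) + 1 if t[-1] >= b0 - _TOL else 0
    if t[-1] + _TOL < needed:
        raise ValueError(
            f"trace covers {available} cycle(s); {n_cycles} requested "
            f"(needs data through t={needed + t0_min} min)"
        )

    swelling = []
    prev_peak_end = t[0]
    for i in range(n_cycles):
        a_i, b_i = i * cycle + a0, i * cycle + b0
        if peak_window == "full_cycle":
            win_lo, win_hi = i * cycle, (i + 1) * cycle
        else:
            win_lo, win_hi = a_i, b_i + peak_lag_min
        trough_sel = (t >= prev_peak_end - _TOL) & (t <= a_i + _TOL)
        if not trough_sel.any():  # degenerate: use nearest sample at/before a_i
            trough_sel = t <= a_i + _TOL
            if not trough_sel.any():
                trough_sel = np.zeros_like(t, dtype=bool)
                trough_sel[0] = True
        peak_sel = (t >= win_lo - _TOL) & (t <= win_hi + _TOL)
        if not peak_sel.any():
            raise ValueError(f"no samples in peak window of cycle {i}")
        trough = float(v[trough_sel].min())
        peak = float(v[peak_sel].max())
        swelling.append(100.0 * (peak - trough) / trough)
        prev_peak_end = win_hi
    arr = np.asarray(swelling)
    sd = float(arr.std(ddof=1)) if n_cycles > 1 else 0.0
    return SwellingSummary(
        per_cycle_pct=arr,
        mean_pct=float(arr.mean()),
        sd_pct=sd,
        n_cycles=n_cycles,
        n_spheroids=n_spheroids,
    )


def cell_size_timecourse(
    segmentations: dict[str, Sequence[Sequence[CellSegmentation]]],
    timestamps_min: Sequence[float],
) -> pd.DataFrame:
    """Mean cell area +/- SE vs time, pooling cells across spheroids.

    ``segmentations[condition][t]`` is the list of per-spheroid
    :class:`CellSegmentation` at timepoint ``t``.  Cells are pooled across
    spheroids within a condition; the mean is also expressed as percent
    change from the condition's first timepoint.  Timepoints with zero
    retained cells yield NaN and ``missing=True``.
    """
    timestamps = np.asarray(timestamps_min, dtype=float)
    rows = []
    for cond, per_time in segmentations.items():
        if len(per_time) != len(timestamps):
            raise ValueError(
                f"condition {cond!r}: {len(per_time)} timepoints vs "
                f"{len(timestamps)} timestamps"
            )
        baseline = None
        for t_idx, segs in enumerate(per_time):
            pooled = (
                np.concatenate([s.areas_um2 for s in segs])
                if segs
                else np.array([])
            )
            n = len(pooled)
            if n == 0:
                mean = se = pct = np.nan
                missing = True
            else:
                mean = float(pooled.mean())
                se = float(pooled.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
                if baseline is None:
                    baseline = mean
                pct = 100.0 * (mean - baseline) / baseline
                missing = False
            rows.append(
                {
                    "condition": cond,
                    "t_min": timestamps[t_idx],
                    "n_cells": n,
                    "mean_area_um2": mean,
                    "se_um2": se,
                    "pct_change": pct,
                    "missing": missing,
                }
            )
    return pd.DataFrame(rows)


def compare_cell_distributions(
    areas_a: Sequence[float], areas_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two cell-area samples.

    Returns ``(U, p)`` with U the statistic of the first sample (number of
    (a, b) pairs with a > b, ties counting 1/2) and p from the
    tie-corrected normal approximation.
    """
    a = np.asarray(areas_a, dtype=float)
    b = np.asarray(areas_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
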