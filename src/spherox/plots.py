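"""Figure helpers mirroring the standard panels of a cycling-hypoxia
spheroid study: area time courses with SE bands over the oxygen trace,
per-cycle swelling bars, accumulation curves, and penetration profiles."""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .schedule import OxygenSchedule
from .swelling import MeanTrace, SwellingSummary
from .uptake import PenetrationProfile


def _save(fig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_swelling_timecourse(
    mean_trace: MeanTrace,
    schedule: Optional[OxygenSchedule],
    path: str | Path,
) -> Path:
    """Cohort-mean normalized area with SE band; oxygen trace below."""
    if schedule is not None:
        fig, (ax, ax_o2) = plt.subplots(
            2, 1, sharex=True, height_ratios=[3, 1], figsize=(7, 4.5)
        )
    else:
        fig, ax = plt.subplots(figsize=(7, 3.5))
        ax_o2 = None
    t_h = mean_trace.timestamps_min / 60.0
    ax.plot(t_h, mean_trace.mean_pct, color="tab:blue", lw=1.5)
    ax.fill_between(
        t_h,
        mean_trace.mean_pct - mean_trace.se_pct,
        mean_trace.mean_pct + mean_trace.se_pct,
        alpha=0.3,
        color="tab:blue",
        label=f"mean ± SE (N={mean_trace.n})",
    )
    ax.set_ylabel("spheroid area (% of t=0)")
    ax.legend(frameon=False, fontsize=8)
    if ax_o2 is not None:
        steps_t, steps_o2 = [], []
        for a, b, o2 in schedule.intervals():
            steps_t += [a / 60.0, b / 60.0]
            steps_o2 += [o2, o2]
        ax_o2.plot(steps_t, steps_o2, color="tab:red")
        ax_o2.set_ylabel("O$_2$ (%)")
        ax_o2.set_xlabel("time (h)")
    else:
        ax.set_xlabel("time (h)")
    return _save(fig, path)


def plot_per_cycle(summary: SwellingSummary, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(4, 3))
    idx = np.arange(1, summary.n_cycles + 1)
    ax.bar(idx, summary.per_cycle_pct, color="tab:blue", alpha=0.8)
    ax.axhline(summary.mean_pct, color="k", ls="--", lw=1,
               label=f"mean {summary.mean_pct:.1f} ± {summary.sd_pct:.1f}% (SD)")
    ax.set_xlabel("cycle")
    ax.set_ylabel("per-cycle swelling (%)")
    ax.set_xticks(idx)
    ax.legend(frameon=False, fontsize=8)
    return _save(fig, path)


def plot_cell_timecourse(df: pd.DataFrame, path: str | Path) -> Path:
    """Mean cell-area percent change vs time, one band per condition."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for cond, g in df.groupby("condition"):
        g = g.sort_values("t_min")
        base = g["mean_area_um2"].iloc[0]
        se_pct = 100.0 * g["se_um2"] / base
        ax.plot(g["t_min"], g["pct_change"], label=str(cond), lw=1.5)
        ax.fill_between(
            g["t_min"], g["pct_change"] - se_pct, g["pct_change"] + se_pct, alpha=0.3
        )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("cell area change (%)")
    ax.legend(frameon=False, fontsize=8, title="condition")
    return _save(fig, path)


def plot_accumulation(df: pd.DataFrame, path: str | Path) -> Path:
    """Cohort doxorubicin accumulation vs time per condition."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for cond, g in df.groupby("condition"):
        g = g.sort_values("t_min")
        ax.plot(g["t_min"] / 60.0, g["mean"], label=str(cond), lw=1.5)
        ax.fill_between(g["t_min"] / 60.0, g["mean"] - g["se"], g["mean"] + g["se"], alpha=0.3)
    ax.set_xlabel("time (h)")
    ax.set_ylabel("mean dox intensity (a.u.)")
    ax.legend(frameon=False, fontsize=8, title="condition")
    return _save(fig, path)


def plot_penetration(
    profiles: Sequence[tuple[str, PenetrationProfile]], path: str | Path
) -> Path:
    """Intensity vs depth into the spheroid; guard region shaded."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    guard_max = 0.0
    for label, prof in profiles:
        ax.plot(prof.bin_centers_um, prof.mean_intensity, label=label, lw=1.5)
        if prof.guard_flags.any():
            guard_max = max(guard_max, prof.bin_edges_um[:-1][prof.guard_flags].max())
    if guard_max > 0:
        ax.axvspan(0, guard_max, color="gray", alpha=0.15, label="edge guard")
    ax.set_xlabel("depth into spheroid (µm)")
    ax.set_ylabel("mean dox intensity (a.u.)")
    ax.legend(frameon=False, fontsize=8)
    return _save(fig, path)
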