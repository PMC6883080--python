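"""End-to-end phantom cohort studies.

These functions wire the full pipeline — phantom generation, segmentation,
tracking, swelling/cell statistics — for the three canonical experiment
layouts the package targets:

* brightfield swelling cohorts under three cycling-oxygen profiles
  (shell-free mature spheroids and smaller in-shell spheroids), with the
  ground-truth per-cycle area swelling programmed to a requested cohort
  mean;
* a two-condition membrane-stain study (severe hypoxia vs normoxia) whose
  hypoxic cohort carries programmed first-order cell swelling, compared
  per timepoint by Mann-Whitney U test.

Cohort layouts (spheroid counts, radii, schedules, programmed amplitudes)
are study conditions, fixed here; only the seed varies between runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import (
    AnalysisParams,
    ImagingParams,
    PhantomParams,
    SegmentationParams,
    SwellingKinetics,
)
from .phantom import calibrate_swelling_amplitude, generate_cohort
from .schedule import OxygenSchedule
from .segmentation import segment_cells, segment_spheroid_frame, track_spheroids
from .swelling import (
    cohort_mean_se,
    compare_cell_distributions,
    normalize_trace,
    per_cycle_swelling,
)


@dataclass(frozen=True)
class SwellingCohortSpec:
    """One brightfield swelling cohort: schedule + geometry + programmed
    per-cycle swelling."""

    schedule: OxygenSchedule
    n_spheroids: int
    base_radii_um: tuple[float, ...]
    has_shell: bool
    programmed_pct: float
    fov_px: int


SWELLING_COHORTS: dict[str, SwellingCohortSpec] = {
    # mature spheroids that migrated out of their shells, 12 h cycles
    "shell_free_2h0_6h3_4h10": SwellingCohortSpec(
        schedule=OxygenSchedule([(120, 0.0), (360, 3.0), (240, 10.0)], repeat_count=3),
        n_spheroids=5,
        base_radii_um=(70.0, 75.0, 80.0, 72.0, 78.0),
        has_shell=False,
        programmed_pct=14.0,
        fov_px=224,
    ),
    # smaller spheroids still inside alginate shells, 6 h cycles
    "in_shell_2h0_2h3_2h10": SwellingCohortSpec(
        schedule=OxygenSchedule([(120, 0.0), (120, 3.0), (120, 10.0)], repeat_count=3),
        n_spheroids=6,
        base_radii_um=(42.0, 45.0, 48.0, 44.0, 47.0, 43.0),
        has_shell=True,
        programmed_pct=7.1,
        fov_px=160,
    ),
    # in-shell spheroids, two-level 9 h cycles
    "in_shell_3h0_6h10": SwellingCohortSpec(
        schedule=OxygenSchedule([(180, 0.0), (360, 10.0)], repeat_count=3),
        n_spheroids=5,
        base_radii_um=(42.0, 46.0, 48.0, 44.0, 45.0),
        has_shell=True,
        programmed_pct=11.0,
        fov_px=160,
    ),
}

FRAME_INTERVAL_MIN = 30.0
TAU_MIN = 30.0


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def swelling_recovery_study(
    cohort: str,
    seed: int,
    noise: bool = True,
    n_cycles: int = 3,
) -> dict:
    """Run segment -> track -> normalize -> per-cycle swelling on a phantom
    cohort whose ground-truth per-cycle swelling equals the programmed value.

    Returns the measured cohort per-cycle swelling (mean over the first
    ``n_cycles`` cycles of the cohort-mean trace) alongside the programmed
    ground truth.
    """
    spec = SWELLING_COHORTS[cohort]
    analysis = AnalysisParams(n_cycles=n_cycles)
    s_eq = calibrate_swelling_amplitude(
        spec.programmed_pct,
        spec.schedule,
        tau_min=TAU_MIN,
        n_cycles=n_cycles,
        dt_min=FRAME_INTERVAL_MIN,
        peak_lag_min=analysis.peak_lag_min,
    )
    n_frames = int(math.floor(spec.schedule.total_min / FRAME_INTERVAL_MIN)) + 1
    params = PhantomParams(
        n_spheroids=spec.n_spheroids,
        base_radius_um=list(spec.base_radii_um),
        has_shell=spec.has_shell,
        swelling=SwellingKinetics(s_eq=s_eq, tau_min=TAU_MIN, s0=1.0),
        imaging=ImagingParams(
            fov_px=spec.fov_px,
            frame_interval_min=FRAME_INTERVAL_MIN,
            photon_scale=200.0 if noise else None,
            read_noise_sd=0.01 if noise else 0.0,
        ),
        n_frames=n_frames,
        seed=_child_seed(seed, 0),
    )
    seg_params = SegmentationParams()
    traces = []
    for i, (stack, gt) in enumerate(generate_cohort(params, spec.schedule, "brightfield")):
        tracks = [tr for tr in track_spheroids(stack, seg_params) if tr.complete()]
        if not tracks:
            raise RuntimeError(f"spheroid {i}: no complete track")
        tr = max(tracks, key=lambda t: np.nanmean(t.areas_um2))
        traces.append(normalize_trace(tr.areas_um2, tr.timestamps_min, str(i)))
    mean_trace = cohort_mean_se(traces).as_trace()
    summary = per_cycle_swelling(
        mean_trace,
        spec.schedule,
        n_cycles=n_cycles,
        peak_lag_min=analysis.peak_lag_min,
        n_spheroids=spec.n_spheroids,
    )
    return {
        "measured_pct": summary.mean_pct,
        "sd_pct": summary.sd_pct,
        "per_cycle_pct": summary.per_cycle_pct.tolist(),
        "programmed_pct": spec.programmed_pct,
        "n_spheroids": spec.n_spheroids,
    }


# membrane-stain two-condition study layout
CELL_STUDY = {
    "n_spheroids": 3,
    "base_radius_um": 150.0,
    "mean_cell_radius_um": 6.0,
    "fov_px": 352,
    "frame_interval_min": 40.0,
    "n_frames": 7,
    "area_swell_frac": 0.11,  # hypoxic cell-area gain by the final timepoint
    "cell_tau_min": 60.0,  # sub-hour onset: cells respond within the first interval
}


def cell_significance_study(seed: int) -> dict:
    """Two-condition single-cell swelling comparison on membrane phantoms.

    The hypoxic (0% O2) cohort carries first-order cell-area swelling of
    ~11% by the final timepoint; the normoxic (20% O2) control is static.
    Cells are segmented at every timepoint, pooled across the cohort's
    spheroids, and the distributions compared by two-sided Mann-Whitney U at
    every post-baseline timepoint.
    """
    cs = CELL_STUDY
    duration = cs["frame_interval_min"] * cs["n_frames"]
    s_eq_swell = math.sqrt(1.0 + cs["area_swell_frac"])
    t_final = cs["frame_interval_min"] * (cs["n_frames"] - 1)
    # rescale the equilibrium so the *final-timepoint* gain hits the target
    reached = 1.0 - math.exp(-t_final / cs["cell_tau_min"])
    s_eq_swell = 1.0 + (s_eq_swell - 1.0) / reached

    conditions = {
        "0pct": (OxygenSchedule([(duration, 0.0)]), {0.0: s_eq_swell}),
        "20pct": (OxygenSchedule([(duration, 20.0)]), {20.0: 1.0}),
    }
    seg_params = SegmentationParams()
    pooled: dict[str, list[np.ndarray]] = {}
    timestamps = None
    for c_idx, (cond, (sched, s_eq)) in enumerate(conditions.items()):
        params = PhantomParams(
            n_spheroids=cs["n_spheroids"],
            base_radius_um=cs["base_radius_um"],
            mean_cell_radius_um=cs["mean_cell_radius_um"],
            swelling=SwellingKinetics(s_eq=s_eq, tau_min=cs["cell_tau_min"], s0=1.0),
            imaging=ImagingParams(
                fov_px=cs["fov_px"], frame_interval_min=cs["frame_interval_min"]
            ),
            n_frames=cs["n_frames"],
            seed=_child_seed(seed, 1, c_idx),
        )
        per_time = [[] for _ in range(cs["n_frames"])]
        for stack, gt in generate_cohort(params, sched, "membrane"):
            for t in range(stack.n_frames):
                frame = stack.frame(t)
                mask = segment_spheroid_frame(frame, seg_params)
                seg = segment_cells(
                    frame, mask, seg_params, pixel_size_um=stack.pixel_size_um
                )
                per_time[t].append(seg.areas_um2)
            timestamps = stack.timestamps_min
        pooled[cond] = [np.concatenate(p) for p in per_time]

    p_values, n_cells = [], []
    for t in range(1, cs["n_frames"]):
        _, p = compare_cell_distributions(pooled["0pct"][t], pooled["20pct"][t])
        p_values.append(p)
        n_cells.append(min(len(pooled["0pct"][t]), len(pooled["20pct"][t])))
    return {
        "p_values": p_values,
        "max_p": max(p_values),
        "min_cells_per_group": min(n_cells),
        "timestamps_min": timestamps.tolist() if timestamps is not None else [],
    }


def psf_resolutions() -> dict:
    """Diffraction-limited two-photon PSF widths for the default objective."""
    from .optics import axial_resolution, lateral_resolution

    return {
        "lateral_um": lateral_resolution(810.0, 1.05),
        "axial_um": axial_resolution(810.0, 1.05, 1.33),
    }
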