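"""Ground-truthed synthetic microscopy phantoms of tumour spheroids.

The phantom generator emulates the three imaging channels of a
cycling-hypoxia spheroid experiment:

``brightfield``
    Transmitted-light time-lapse: the spheroid is a dark, textured disk on a
    bright background, optionally surrounded by a faint alginate-shell ring
    that does not follow the swelling.
``membrane``
    Membrane-stain fluorescence: cells laid out by centroidal Voronoi
    tessellation of the spheroid disk, with bright ridges at cell boundaries.
``dox``
    Doxorubicin fluorescence: an edge-to-centre reaction-diffusion gradient
    modulated by per-cell lognormal heterogeneity and depth-dependent
    optical attenuation.

The spheroid's linear scale factor s(t) relaxes first-order toward an
oxygen-dependent equilibrium as the gas schedule switches levels, so the
ground-truth projected area of an unconfined spheroid is pi*(s(t)*r0)^2.
All renders are blurred with the Gaussian two-photon PSF and carry Poisson
photon noise plus Gaussian read noise.  Identical (params, schedule, seed)
produce bit-identical stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import solve_banded
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.segmentation import find_boundaries

from .config import DoxParams, PhantomParams
from .io import ImageStack, log
from .optics import PSFModel
from .schedule import OxygenSchedule

PACKING_FRACTION = 0.9  # 2D cell packing used to derive cell counts

MODALITIES = ("brightfield", "membrane", "dox")


# ---------------------------------------------------------------------------
# Swelling kinetics


def simulate_swelling_trace(
    schedule: OxygenSchedule,
    s_eq: Mapping[float, float],
    tau_min: float,
    duration_min: float,
    dt_min: float,
    s0: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """First-order relaxation of the linear scale factor under a gas schedule.

    Integrates ``ds/dt = (s_eq(o2(t)) - s) / tau`` exactly (piecewise
    exponential, sub-stepping at phase boundaries) and samples on the fixed
    grid ``0, dt, 2*dt, ...`` up to ``duration_min``.

    Parameters
    ----------
    s_eq:
        Map from oxygen level (% of 1 atm) to equilibrium scale factor; must
        cover every level in the schedule.
    s0:
        Initial scale factor; default is the equilibrium of the first phase.

    Returns
    -------
    (times_min, s) arrays; ``s > 0`` everywhere.
    """
    if not dt_min > 0:
        raise ValueError(f"dt_min must be > 0, got {dt_min}")
    if not tau_min > 0:
        raise ValueError(f"tau_min must be > 0, got {tau_min}")
    if duration_min > schedule.total_min + 1e-9:
        raise ValueError(
            f"duration {duration_min} min exceeds schedule total "
            f"{schedule.total_min} min"
        )
    missing = [o2 for o2 in schedule.o2_levels() if o2 not in s_eq]
    if missing:
        raise ValueError(f"s_eq missing entries for scheduled o2 levels: {missing}")
    for o2, s in s_eq.items():
        if not s > 0:
            raise ValueError(f"s_eq[{o2}] must be > 0, got {s}")

    times = np.arange(0.0, duration_min + dt_min / 2, dt_min)
    intervals = [
        (a, b, o2) for a, b, o2 in schedule.intervals() if a < duration_min + 1e-9
    ]
    s = np.empty_like(times)
    cur = float(s_eq[intervals[0][2]] if s0 is None else s0)
    if not cur > 0:
        raise ValueError(f"s0 must be > 0, got {s0}")
    s[0] = cur
    t_cur = 0.0
    for k in range(1, len(times)):
        t_next = times[k]
        # step exactly across every constant-o2 sub-interval in (t_cur, t_next]
        for a, b, o2 in intervals:
            lo, hi = max(a, t_cur), min(b, t_next)
            if hi <= lo + 1e-12:
                continue
            eq = float(s_eq[o2])
            cur = eq + (cur - eq) * math.exp(-(hi - lo) / tau_min)
        t_cur = t_next
        s[k] = cur
    return times, s


def calibrate_swelling_amplitude(
    target_pct: float,
    schedule: OxygenSchedule,
    tau_min: float = 30.0,
    n_cycles: int = 3,
    dt_min: float = 30.0,
    peak_lag_min: float = 60.0,
    mid_level_fraction: float = 0.25,
    s0: float = 1.0,
) -> dict[float, float]:
    """Equilibrium scale-factor map whose ground-truth per-cycle area swelling
    equals ``target_pct``.

    The most hypoxic schedule level gets the free amplitude ``A``, the least
    hypoxic level 1.0, and intermediate levels ``1 + mid_level_fraction*(A-1)``.
    ``A`` is found by root-finding the per-cycle swelling statistic evaluated
    on the exact noise-free trace sampled at ``dt_min``.
    """
    from scipy.optimize import brentq

    from .swelling import normalize_trace, per_cycle_swelling

    levels = sorted(schedule.o2_levels())
    if len(levels) < 2:
        raise ValueError("calibration needs a schedule with >= 2 oxygen levels")
    if not target_pct >= 0:
        raise ValueError(f"target_pct must be >= 0, got {target_pct}")

    def s_eq_for(amp: float) -> dict[float, float]:
        out = {}
        for o2 in levels:
            if o2 == levels[0]:
                out[o2] = amp
            elif o2 == levels[-1]:
                out[o2] = 1.0
            else:
                out[o2] = 1.0 + mid_level_fraction * (amp - 1.0)
        return out

    def measured(amp: float) -> float:
        times, s = simulate_swelling_trace(
            schedule, s_eq_for(amp), tau_min, schedule.total_min, dt_min, s0=s0
        )
        trace = normalize_trace((s / s[0]) ** 2, times)
        summary = per_cycle_swelling(
            trace, schedule, n_cycles=n_cycles, peak_lag_min=peak_lag_min
        )
        return summary.mean_pct

    if target_pct == 0:
        return s_eq_for(1.0)
    amp = brentq(lambda a: measured(a) - target_pct, 1.0, 3.0, xtol=1e-10)
    return s_eq_for(float(amp))


# ---------------------------------------------------------------------------
# Cell layout


def cvt_disk_points(
    n_cells: int,
    radius_um: float,
    rng: np.random.Generator,
    n_iter: int = 10,
    grid_res_um: float = 1.5,
) -> np.ndarray:
    """Centroidal Voronoi tessellation seeds in a disk (Lloyd relaxation).

    Returns (n_cells, 2) seed coordinates in um relative to the disk centre.
    A stand-in for packed epithelial geometry: near-uniform cell sizes with
    natural area scatter.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    # uniform random start
    theta = rng.uniform(0, 2 * np.pi, n_cells)
    rad = radius_um * np.sqrt(rng.uniform(0, 1, n_cells))
    seeds = np.column_stack([rad * np.cos(theta), rad * np.sin(theta)])
    # candidate points: dense grid inside the disk
    n_grid = max(32, int(round(2 * radius_um / grid_res_um)))
    ax = np.linspace(-radius_um, radius_um, n_grid)
    xx, yy = np.meshgrid(ax, ax)
    inside = xx**2 + yy**2 <= radius_um**2
    pts = np.column_stack([xx[inside], yy[inside]])
    for _ in range(n_iter):
        _, lab = cKDTree(seeds).query(pts)
        sums = np.zeros((n_cells, 2))
        counts = np.zeros(n_cells)
        np.add.at(sums, lab, pts)
        np.add.at(counts, lab, 1.0)
        nonempty = counts > 0
        seeds[nonempty] = sums[nonempty] / counts[nonempty, None]
    return seeds


def derived_cell_count(radius_um: float, mean_cell_radius_um: float) -> int:
    """Cell count from 2D packing of the spheroid mid-plane disk."""
    return max(1, int(round(PACKING_FRACTION * (radius_um / mean_cell_radius_um) ** 2)))


# ---------------------------------------------------------------------------
# Doxorubicin reaction-diffusion field


def simulate_dox_field(
    radius_um: float,
    dox_params: DoxParams,
    times_min: Sequence[float],
    n_r: int = 201,
    dt_min: float = 0.25,
) -> tuple[np.ndarray, np.ndarray]:
    """Radial doxorubicin concentration in a sphere bathed at C=1.

    Solves ``dC/dt = D * (1/r^2) d/dr(r^2 dC/dr) - k*C`` with ``C(r,0)=0``,
    ``C(R,t)=1`` and no-flux at the centre, via the substitution ``u = r*C``
    (a plain 1D diffusion-decay equation with ``u(0)=0``, ``u(R)=R``),
    integrated by implicit Euler on a uniform radial grid.  The implicit
    scheme's M-matrix structure preserves the physical monotonicity: C is
    non-decreasing in time everywhere and non-increasing from edge to centre.

    Returns
    -------
    (r_um, C) with ``r_um`` shape (n_r,) and ``C`` shape (len(times), n_r).
    """
    D = dox_params.D_um2_per_min
    k = dox_params.k_uptake_per_min
    if not D > 0:
        raise ValueError(f"D must be > 0, got {D}")
    if not k >= 0:
        raise ValueError(f"k must be >= 0, got {k}")
    if not radius_um > 0:
        raise ValueError(f"radius must be > 0, got {radius_um}")
    times = np.asarray(times_min, dtype=float)
    if times.ndim != 1 or len(times) == 0 or np.any(times < 0):
        raise ValueError("times_min must be a non-empty 1D array of >= 0 values")
    if np.any(np.diff(times) <= 0) and len(times) > 1:
        raise ValueError("times_min must be strictly increasing")

    r = np.linspace(0.0, radius_um, n_r)
    dr = r[1] - r[0]
    n_int = n_r - 2  # interior unknowns
    # implicit Euler: (I - dt*(D*L - k*I)) u_new = u_old + boundary source
    alpha = D * dt_min / dr**2
    ab = np.zeros((3, n_int))
    ab[0, 1:] = -alpha
    ab[1, :] = 1.0 + 2.0 * alpha + k * dt_min
    ab[2, :-1] = -alpha

    u = np.zeros(n_r)
    u[-1] = radius_um  # bath C = 1
    C_out = np.zeros((len(times), n_r))
    t_cur = 0.0
    out_idx = 0
    if times[0] == 0.0:
        out_idx = 1  # C(:,0) stays 0
    while out_idx < len(times):
        t_target = times[out_idx]
        n_steps = max(1, int(math.ceil((t_target - t_cur) / dt_min - 1e-12)))
        dt_eff = (t_target - t_cur) / n_steps
        if abs(dt_eff - dt_min) > 1e-12:
            a_eff = D * dt_eff / dr**2
            ab_eff = np.zeros((3, n_int))
            ab_eff[0, 1:] = -a_eff
            ab_eff[1, :] = 1.0 + 2.0 * a_eff + k * dt_eff
            ab_eff[2, :-1] = -a_eff
        else:
            a_eff, ab_eff = alpha, ab
        for _ in range(n_steps):
            rhs = u[1:-1].copy()
            rhs[-1] += a_eff * u[-1]
            u[1:-1] = solve_banded((1, 1), ab_eff, rhs)
        t_cur = t_target
        C = np.empty(n_r)
        C[1:] = u[1:] / r[1:]
        C[0] = u[1] / r[1]  # r->0 limit (u odd-symmetric, u ~ C(0)*r)
        C_out[out_idx] = C
        out_idx += 1
    return r, C_out


def dox_steady_state(radius_um: float, D: float, k: float, r: np.ndarray) -> np.ndarray:
    """Analytic steady profile (R/r)*sinh(r*sqrt(k/D))/sinh(R*sqrt(k/D))."""
    if k == 0:
        return np.ones_like(r)
    q = math.sqrt(k / D)
    out = np.empty_like(r)
    nz = r > 0
    out[nz] = (radius_um / r[nz]) * np.sinh(q * r[nz]) / math.sinh(q * radius_um)
    out[~nz] = q * radius_um / math.sinh(q * radius_um)
    return out


# ---------------------------------------------------------------------------
# Ground truth


@dataclass
class GroundTruth:
    """Everything the renderer knows: the test oracle for the analysis.

    Arrays are indexed per spheroid then per frame.  ``cell_points_um`` and
    ``cell_areas_um2`` describe the base (s=1) mid-plane tessellation; cell
    areas at frame t scale as ``s(t)**2``.
    """

    times_min: np.ndarray
    s: np.ndarray  # (n_spheroids, T)
    true_area_um2: np.ndarray  # (n_spheroids, T)
    centers_px: np.ndarray  # (n_spheroids, 2) row, col
    base_radius_um: np.ndarray  # (n_spheroids,)
    pixel_size_um: float
    modality: str
    cell_points_um: list = field(default_factory=list)
    cell_areas_um2: list = field(default_factory=list)
    label_maps: Optional[list] = None  # per frame (membrane modality, mid slice)
    slice_z_um: Optional[np.ndarray] = None  # Z offsets from sphere centre
    dox_r_um: Optional[np.ndarray] = None
    dox_C: Optional[np.ndarray] = None  # (T, n_r)

    def disk_mask(
        self, frame: int, shape: tuple[int, int], spheroid: int = 0
    ) -> np.ndarray:
        """Analytic boolean mask of spheroid ``spheroid`` at ``frame``."""
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        cy, cx = self.centers_px[spheroid]
        r_px = self.s[spheroid, frame] * self.base_radius_um[spheroid] / self.pixel_size_um
        return (rr - cy) ** 2 + (cc - cx) ** 2 <= r_px**2

    def cell_areas_at(self, frame: int, spheroid: int = 0) -> np.ndarray:
        """True cell areas (um^2) at a frame: base tessellation scaled by s^2."""
        return self.cell_areas_um2[spheroid] * self.s[spheroid, frame] ** 2


# ---------------------------------------------------------------------------
# Rendering


def _heterogeneity_factors(n: int, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-mean lognormal per-cell brightness factors."""
    if cv == 0:
        return np.ones(n)
    sigma = math.sqrt(math.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)


def _apply_noise(
    img: np.ndarray,
    photon_scale: Optional[float],
    read_noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if photon_scale is not None:
        img = rng.poisson(np.clip(img, 0, None) * photon_scale) / photon_scale
    if read_noise_sd > 0:
        img = img + rng.normal(0.0, read_noise_sd, img.shape)
    return np.clip(img, 0.0, None)


def _label_pixels(
    shape: tuple[int, int],
    center_px: tuple[float, float],
    base_radius_px: float,
    tree: cKDTree,
    scale: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(disk mask, label map) for a spheroid scaled by ``scale``.

    The rendered disk radius is ``base_radius_px * scale``; pixel coordinates
    are mapped back to the base tessellation by dividing by the scale factor,
    so all cell linear dimensions follow s(t).
    """
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = rr - center_px[0]
    dx = cc - center_px[1]
    disk = dy**2 + dx**2 <= (base_radius_px * scale) ** 2
    labels = np.zeros(shape, dtype=np.int32)
    if disk.any():
        pts = np.column_stack([dy[disk], dx[disk]]) / scale
        _, lab = tree.query(pts)
        labels[disk] = lab + 1
    return disk, labels


def generate_phantom(
    params: PhantomParams,
    schedule: OxygenSchedule,
    modality: str,
    psf: Optional[PSFModel] = None,
) -> tuple[ImageStack, GroundTruth]:
    """Render a synthetic time-lapse (one field of view) with ground truth.

    Spheroids are placed on a square grid of ``fov_px`` tiles (one per
    trap).  For ``n_z > 1`` (membrane / dox) each frame is a Z-stack of
    sphere cross-sections.  Raises if a swollen spheroid (plus shell) would
    leave its tile.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}; expected one of {MODALITIES}")
    if psf is None:
        psf = PSFModel.diffraction_limited()
    img_p = params.imaging
    p = img_p.pixel_size_um
    n_sph = params.n_spheroids
    radii = np.asarray(params.radii(), dtype=float)

    times = np.arange(params.n_frames, dtype=float) * img_p.frame_interval_min
    if times[-1] > schedule.total_min + 1e-9:
        raise ValueError(
            f"{params.n_frames} frames at {img_p.frame_interval_min} min exceed "
            f"schedule duration {schedule.total_min} min"
        )

    # deterministic per-spheroid RNG streams (modality index keeps channels
    # statistically independent under one seed)
    root_ss = np.random.SeedSequence([params.seed, MODALITIES.index(modality)])
    children = root_ss.spawn(n_sph)

    # shared kinetics: every spheroid in the cohort sees the same gas schedule
    _, s_trace = simulate_swelling_trace(
        schedule,
        params.swelling.s_eq,
        params.swelling.tau_min,
        duration_min=float(times[-1]),
        dt_min=img_p.frame_interval_min,
        s0=params.swelling.s0,
    )
    s_trace = s_trace[: len(times)]
    if not params.has_shell and params.confinement_gain != 1.0:
        # compaction against the channel ceiling inflates the apparent
        # (projected-area) scale change; ground truth carries the same
        # effective s so the area invariant stays exact
        s_trace = 1.0 + params.confinement_gain * (s_trace - 1.0)
    s_all = np.tile(s_trace, (n_sph, 1))

    # layout: square grid of tiles
    n_cols = int(math.ceil(math.sqrt(n_sph)))
    n_rows = int(math.ceil(n_sph / n_cols))
    tile = img_p.fov_px
    shape_yx = (n_rows * tile, n_cols * tile)
    centers = np.array(
        [
            ((i // n_cols) * tile + tile / 2.0, (i % n_cols) * tile + tile / 2.0)
            for i in range(n_sph)
        ]
    )
    s_max = float(s_all.max())
    for i, r0 in enumerate(radii):
        extent = r0 * s_max
        if params.has_shell:
            extent = max(extent, r0 + params.shell_gap_um + params.shell_thickness_um)
        if extent / p > tile / 2.0 - 2:
            raise ValueError(
                f"spheroid {i} (radius {r0} um, max scale {s_max:.3f}) exceeds "
                f"its {tile} px field of view at {p} um/px"
            )

    # per-spheroid tessellation and optical factors
    trees, seeds_um, base_areas, shades, het = [], [], [], [], []
    for i in range(n_sph):
        rng_i = np.random.default_rng(children[i])
        n_cells = params.n_cells or derived_cell_count(radii[i], params.mean_cell_radius_um)
        pts = cvt_disk_points(n_cells, radii[i], rng_i)
        seeds_um.append(pts)
        trees.append(cKDTree(pts / p))  # in pixel units
        # base-scale cell areas from a fine pixel count at rendering resolution
        disk, labels = _label_pixels(
            (int(2 * radii[i] / p) + 5, int(2 * radii[i] / p) + 5),
            (radii[i] / p + 2, radii[i] / p + 2),
            radii[i] / p,
            trees[i],
            1.0,
        )
        counts = np.bincount(labels[disk], minlength=n_cells + 1)[1:]
        base_areas.append(counts.astype(float) * p**2)
        shades.append(np.clip(rng_i.normal(0.0, 0.07, n_cells), -0.2, 0.2))
        het.append(_heterogeneity_factors(n_cells, params.dox.heterogeneity_cv, rng_i))

    # dox concentration field (shared radius scale: per-spheroid base radius)
    dox_r = dox_C = None
    if modality == "dox":
        dox_r, dox_C = simulate_dox_field(float(radii.max()), params.dox, times)

    # Z geometry: slices descend from just above the (unswollen) top surface
    n_z = params.n_z
    if n_z > 1:
        z_offsets = radii.max() + img_p.z_spacing_um / 2.0 - np.arange(n_z) * img_p.z_spacing_um
    else:
        z_offsets = np.array([0.0])

    sigma_px = psf.lateral_sigma_um / p
    noise_rng = np.random.default_rng(root_ss.spawn(1)[0])
    frames = np.empty(
        (len(times), n_z, shape_yx[0], shape_yx[1]) if n_z > 1 else (len(times), *shape_yx),
        dtype=np.float32,
    )
    label_maps: Optional[list] = [] if modality == "membrane" else None

    for t_idx in range(len(times)):
        for z_idx, z_um in enumerate(z_offsets):
            img = np.full(shape_yx, 1.0 if modality == "brightfield" else 0.02)
            labels_frame = np.zeros(shape_yx, dtype=np.int32)
            for i in range(n_sph):
                s = s_all[i, t_idx]
                r_eff_um = radii[i] * s
                if abs(z_um) >= r_eff_um and n_z > 1:
                    continue  # slice above/below the sphere
                r_slice_um = (
                    math.sqrt(max(r_eff_um**2 - z_um**2, 0.0)) if n_z > 1 else r_eff_um
                )
                disk, labels = _label_pixels(
                    shape_yx, tuple(centers[i]), r_slice_um / p / s, trees[i], s
                )
                if not disk.any():
                    continue
                labels_frame[disk] = labels[disk] + labels_frame.max()
                rr, cc = np.nonzero(disk)
                dy = (rr - centers[i][0]) * p
                dx = (cc - centers[i][1]) * p
                r_lat = np.sqrt(dy**2 + dx**2)
                lab0 = labels[disk] - 1
                if modality == "brightfield":
                    rho = np.clip(r_lat / r_eff_um, 0, 1)
                    vals = 0.62 - 0.10 * np.sqrt(1 - rho**2) + shades[i][lab0]
                    img[disk] = np.clip(vals, 0.05, None)
                elif modality == "membrane":
                    inner = 0.10 + 0.3 * shades[i][lab0]
                    img[disk] = np.clip(inner, 0.02, None)
                    ridge = find_boundaries(labels, mode="thick") & disk
                    img[ridge] = 1.0
                else:  # dox
                    r3d = np.sqrt(r_lat**2 + z_um**2) / s  # back to base geometry
                    Ct = np.interp(r3d, dox_r, dox_C[t_idx])
                    path = np.sqrt(np.clip(r_eff_um**2 - r_lat**2, 0, None)) - z_um
                    atten = np.exp(-np.clip(path, 0, None) / params.dox.scatter_length_um)
                    img[disk] = Ct * het[i][lab0] * atten + 0.01
                if params.has_shell and modality == "brightfield":
                    r_in = radii[i] + params.shell_gap_um
                    r_out = r_in + params.shell_thickness_um
                    rr2, cc2 = np.mgrid[0 : shape_yx[0], 0 : shape_yx[1]]
                    r_all = np.sqrt(
                        ((rr2 - centers[i][0]) * p) ** 2 + ((cc2 - centers[i][1]) * p) ** 2
                    )
                    ring = (r_all >= r_in) & (r_all <= r_out)
                    img[ring] -= 0.04  # faint; does not follow s(t)
            img = gaussian_filter(img, sigma_px, mode="nearest")
            img = _apply_noise(img, img_p.photon_scale, img_p.read_noise_sd, noise_rng)
            if n_z > 1:
                frames[t_idx, z_idx] = img
            else:
                frames[t_idx] = img
            if label_maps is not None and (n_z == 1 or z_idx == int(np.argmin(np.abs(z_offsets)))):
                label_maps.append(labels_frame)

    stack = ImageStack(
        data=frames,
        pixel_size_um=p,
        timestamps_min=times,
        z_spacing_um=img_p.z_spacing_um if n_z > 1 else None,
        channel_label=modality,
    )
    gt = GroundTruth(
        times_min=times,
        s=s_all,
        true_area_um2=np.pi * (s_all * radii[:, None]) ** 2,
        centers_px=centers,
        base_radius_um=radii,
        pixel_size_um=p,
        modality=modality,
        cell_points_um=seeds_um,
        cell_areas_um2=base_areas,
        label_maps=label_maps,
        slice_z_um=z_offsets if n_z > 1 else None,
        dox_r_um=dox_r,
        dox_C=dox_C,
    )
    log.info(
        "phantom modality=%s n_spheroids=%d n_frames=%d shape=%s seed=%d",
        modality,
        n_sph,
        len(times),
        frames.shape,
        params.seed,
    )
    return stack, gt


def generate_cohort(
    params: PhantomParams,
    schedule: OxygenSchedule,
    modality: str,
    psf: Optional[PSFModel] = None,
) -> list[tuple[ImageStack, GroundTruth]]:
    """One stack per spheroid (one spheroid per hydrodynamic trap).

    Each spheroid gets its own deterministic child seed derived from
    ``params.seed``, so the cohort is reproducible spheroid-by-spheroid.
    """
    out = []
    radii = params.radii()
    for i in range(params.n_spheroids):
        child_seed = int(
            np.random.SeedSequence([params.seed, i]).generate_state(1)[0] % (2**31)
        )
        p_i = params.model_copy(
            update={"n_spheroids": 1, "base_radius_um": radii[i], "seed": child_seed}
        )
        out.append(generate_phantom(p_i, schedule, modality, psf=psf))
    return out
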