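"""Doxorubicin accumulation and penetration quantification from Z-stacks.

Accumulation is the mean fluorescence intensity in the segmented spheroid
region (total summed pixel intensity divided by pixel count) — per
representative slice and pixel-count-weighted across the whole stack, which
equals the 3D mean over the imaged volume.  Penetration is the mean
intensity binned by Euclidean distance inward from the segmented spheroid
edge.  Because texture-based transmitted-light segmentation tends to
overestimate the spheroid edge, bins shallower than a guard depth
(default 10 um) are flagged: intensity there rises artefactually from the
background toward the true edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt
from skimage.filters import gaussian, threshold_otsu

from .io import ImageStack, log


def select_representative_slice(
    zstack: ImageStack,
    target_depth_um: float,
    frame: int = 0,
    min_area_frac: float = 0.2,
    slice_areas_px: Optional[Sequence[float]] = None,
    object_is_bright: bool = True,
) -> int:
    """Index of the Z slice nearest ``target_depth_um`` below the top surface.

    The top surface is the first slice whose foreground area exceeds
    ``min_area_frac`` of the stack's maximum slice area.  Per-slice areas
    are Otsu-threshold foreground counts unless ``slice_areas_px`` is given.
    Ties in depth resolve to the shallower slice.
    """
    if zstack.data.ndim != 4:
        raise ValueError("representative-slice selection requires a Z-stack")
    if target_depth_um < 0:
        raise ValueError(f"target depth must be >= 0, got {target_depth_um}")
    dz = zstack.z_spacing_um
    n_z = zstack.n_z
    if slice_areas_px is None:
        areas = []
        for z in range(n_z):
            sl = gaussian(zstack.frame(frame, z).astype(float), 1.0, preserve_range=True)
            if sl.max() == sl.min():
                areas.append(0.0)
                continue
            thr = threshold_otsu(sl)
            fg = sl > thr if object_is_bright else sl < thr
            areas.append(float(fg.sum()))
        areas = np.asarray(areas)
    else:
        areas = np.asarray(slice_areas_px, dtype=float)
        if len(areas) != n_z:
            raise ValueError(f"expected {n_z} slice areas, got {len(areas)}")
    if areas.max() <= 0:
        raise ValueError("no foreground in any slice; cannot locate surface")
    surface = int(np.argmax(areas >= min_area_frac * areas.max()))
    available_um = (n_z - 1 - surface) * dz
    if target_depth_um > available_um + 1e-9:
        raise ValueError(
            f"stack only reaches {available_um:.1f} um below the surface "
            f"(slice {surface}); target depth {target_depth_um} um unavailable"
        )
    offset = target_depth_um / dz
    lo = int(np.floor(offset))
    hi = lo + 1
    d_lo, d_hi = offset - lo, hi - offset
    pick = lo if d_lo <= d_hi else hi  # tie -> shallower
    return surface + min(pick, n_z - 1 - surface)


def mean_intensity_in_mask(slice2d: np.ndarray, mask: np.ndarray) -> float:
    """Total summed pixel intensity in the mask divided by its pixel count."""
    img = np.asarray(slice2d, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ValueError(f"slice {img.shape} and mask {m.shape} shapes differ")
    if not m.any():
        raise ValueError("empty mask")
    return float(img[m].sum() / m.sum())


def _background_median(slice2d: np.ndarray, mask: np.ndarray) -> float:
    outside = ~mask
    if not outside.any():
        return 0.0
    return float(np.median(np.asarray(slice2d, dtype=float)[outside]))


def accumulation_timecourse(
    stack: ImageStack,
    masks: Sequence[Sequence[Optional[np.ndarray]]],
    condition: str,
    spheroid_id: int = 0,
    representative_slice: Optional[int] = None,
    background_subtract: bool = True,
) -> pd.DataFrame:
    """Per-timepoint doxorubicin accumulation for one spheroid.

    ``masks[t][z]`` is the segmented spheroid mask for frame ``t``, slice
    ``z`` (None where segmentation failed).  Returns one row per timepoint
    with the representative-slice mean, the pixel-count-weighted whole-stack
    mean, and a ``missing`` flag where no slice had a mask.  The per-slice
    background (median outside the mask) is subtracted when
    ``background_subtract`` to stabilise cross-condition comparison.
    """
    if stack.data.ndim != 4:
        raise ValueError("accumulation timecourse requires a Z-stack")
    T, n_z = stack.n_frames, stack.n_z
    if len(masks) != T:
        raise ValueError(f"expected masks for {T} frames, got {len(masks)}")
    rep = representative_slice if representative_slice is not None else n_z // 2
    rows = []
    for t in range(T):
        if len(masks[t]) != n_z:
            raise ValueError(f"frame {t}: expected {n_z} slice masks")
        total, n_px, rep_mean = 0.0, 0, np.nan
        for z in range(n_z):
            m = masks[t][z]
            if m is None or not np.asarray(m, dtype=bool).any():
                continue
            m = np.asarray(m, dtype=bool)
            sl = stack.frame(t, z).astype(float)
            if background_subtract:
                sl = sl - _background_median(sl, m)
            mean_z = mean_intensity_in_mask(sl, m)
            if z == rep:
                rep_mean = mean_z
            total += mean_z * m.sum()
            n_px += int(m.sum())
        missing = n_px == 0
        rows.append(
            {
                "condition": condition,
                "spheroid_id": spheroid_id,
                "t_min": stack.timestamps_min[t],
                "slice_mean": rep_mean,
                "stack_mean": total / n_px if n_px else np.nan,
                "n_px": n_px,
                "missing": missing,
            }
        )
        if missing:
            log.warning(
                "missing segmentation condition=%s spheroid=%d t=%s",
                condition,
                spheroid_id,
                stack.timestamps_min[t],
            )
    return pd.DataFrame(rows)


def cohort_accumulation(per_spheroid: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Cohort mean +/- SE of the whole-stack accumulation per condition and
    timepoint."""
    df = pd.concat(per_spheroid, ignore_index=True)
    def _agg(g: pd.DataFrame) -> pd.Series:
        v = g["stack_mean"].dropna()
        n = len(v)
        return pd.Series(
            {
                "mean": v.mean() if n else np.nan,
                "se": v.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
                "n": n,
            }
        )
    out = (
        df.groupby(["condition", "t_min"])[["stack_mean"]]
        .apply(_agg)
        .reset_index()
    )
    return out


@dataclass
class PenetrationProfile:
    """Mean intensity vs depth inward from the segmented spheroid edge."""

    bin_edges_um: np.ndarray  # strictly increasing from 0, length n_bins+1
    mean_intensity: np.ndarray  # NaN where a bin holds no pixels
    n_pixels: np.ndarray
    guard_flags: np.ndarray  # True where the bin is shallower than the guard
    t_min: float = np.nan

    def __post_init__(self) -> None:
        if self.bin_edges_um[0] != 0 or np.any(np.diff(self.bin_edges_um) <= 0):
            raise ValueError("bin edges must increase strictly from 0")
        if np.any(self.n_pixels < 0):
            raise ValueError("pixel counts must be >= 0")

    @property
    def bin_centers_um(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_um[:-1] + self.bin_edges_um[1:])


def penetration_profile(
    slice2d: np.ndarray,
    mask: np.ndarray,
    bin_width_um: float,
    pixel_size_um: float = 1.0,
    guard_depth_um: float = 10.0,
    t_min: float = np.nan,
) -> PenetrationProfile:
    """Bin mask pixels by Euclidean distance from the mask edge (in um) and
    average the intensity per bin."""
    img = np.asarray(slice2d, dtype=float)
    m = np.asarray(mask, dtype=bool)
    if img.shape != m.shape:
        raise ValueError(f"slice {img.shape} and mask {m.shape} shapes differ")
    if not m.any():
        raise ValueError("empty mask")
    if not bin_width_um > 0:
        raise ValueError(f"bin width must be > 0, got {bin_width_um}")
    depth_um = distance_transform_edt(m) * pixel_size_um
    d = depth_um[m]
    vals = img[m]
    n_bins = int(np.ceil(d.max() / bin_width_um)) or 1
    idx = np.minimum((d / bin_width_um).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    edges = np.arange(n_bins + 1) * bin_width_um
    guard = edges[:-1] < guard_depth_um
    return PenetrationProfile(
        bin_edges_um=edges,
        mean_intensity=means,
        n_pixels=counts,
        guard_flags=guard,
        t_min=t_min,
    )
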