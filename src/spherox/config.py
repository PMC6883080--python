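"""Validated parameter models for the phantom generator and analysis pipeline.

All user-facing configuration flows through these pydantic models: every
field is range-checked before any computation runs, unknown keys are
rejected, and units are spelled out in the key names (``tau_min``,
``pixel_size_um``, ...).
"""

from __future__ import annotations

from typing import Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .schedule import O2_MAX_PCT, OxygenSchedule


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ScheduleConfig(_Model):
    """Serializable form of an :class:`~spherox.schedule.OxygenSchedule`."""

    phases: list[tuple[float, float]] = Field(
        description="(duration_min, o2_pct) pairs for one cycle"
    )
    repeat_count: int = Field(default=1, ge=1)

    @field_validator("phases")
    @classmethod
    def _check_phases(cls, v):
        if not v:
            raise ValueError("phases must be non-empty")
        for duration, o2 in v:
            if not duration > 0:
                raise ValueError(f"duration_min must be > 0, got {duration}")
            if not 0.0 <= o2 <= O2_MAX_PCT:
                raise ValueError(f"o2 must be in [0, {O2_MAX_PCT}], got o2={o2}")
        return v

    def build(self) -> OxygenSchedule:
        return OxygenSchedule(self.phases, repeat_count=self.repeat_count)


class SwellingKinetics(_Model):
    """First-order relaxation of the spheroid linear scale factor.

    ``s_eq`` maps oxygen level (% of 1 atm) to the equilibrium linear scale
    factor; ``tau_min`` is the relaxation time constant.  The default tau of
    30 min makes a 2 h plateau reach >98% of its equilibrium, matching the
    observed sub-hour onset of swelling after a gas switch.
    """

    s_eq: dict[float, float] = Field(
        default_factory=lambda: {0.0: 1.05, 3.0: 1.01, 10.0: 1.0, 20.0: 1.0}
    )
    tau_min: float = Field(default=30.0, gt=0)
    s0: Optional[float] = Field(
        default=None,
        description="initial scale factor; None means s_eq of the first phase",
    )

    @field_validator("s_eq")
    @classmethod
    def _check_s_eq(cls, v):
        for o2, s in v.items():
            if not 0.0 <= o2 <= O2_MAX_PCT:
                raise ValueError(f"s_eq key o2={o2} outside [0, {O2_MAX_PCT}]")
            if not s > 0:
                raise ValueError(f"s_eq[{o2}] must be > 0, got {s}")
        return v


class DoxParams(_Model):
    """Doxorubicin transport, uptake, and optical parameters."""

    D_um2_per_min: float = Field(default=60.0, gt=0, description="diffusivity")
    k_uptake_per_min: float = Field(default=0.02, ge=0, description="first-order uptake")
    heterogeneity_cv: float = Field(
        default=0.3, ge=0, description="per-cell lognormal CV of rendered intensity"
    )
    scatter_length_um: float = Field(
        default=80.0, gt=0, description="optical attenuation length in the spheroid"
    )


class ImagingParams(_Model):
    """Acquisition geometry, calibration, and noise."""

    pixel_size_um: float = Field(default=1.0, gt=0)
    frame_interval_min: float = Field(default=30.0, gt=0)
    z_spacing_um: float = Field(default=4.0, gt=0)
    fov_px: int = Field(default=256, ge=32, description="square field of view, pixels")
    photon_scale: Optional[float] = Field(
        default=200.0,
        gt=0,
        description="photon counts at unit intensity (Poisson noise); None = noise-free",
    )
    read_noise_sd: float = Field(default=0.01, ge=0)


class PhantomParams(_Model):
    """Full description of a synthetic spheroid imaging experiment.

    Identical ``(params, schedule, seed)`` produce bit-identical stacks.
    """

    n_spheroids: int = Field(default=1, ge=1)
    base_radius_um: float | list[float] = Field(
        default=75.0, description="spheroid radius at scale factor 1, per spheroid"
    )
    has_shell: bool = Field(
        default=False, description="render a non-swelling alginate shell ring"
    )
    shell_thickness_um: float = Field(default=12.0, gt=0)
    shell_gap_um: float = Field(
        default=10.0, gt=0, description="clearance between spheroid and shell"
    )
    confinement_gain: float = Field(
        default=1.0,
        ge=1.0,
        description="area-change inflation for shell-free spheroids compacted "
        "against the channel ceiling (projected area over-states volume change)",
    )
    mean_cell_radius_um: float = Field(default=6.0, gt=0)
    n_cells: Optional[int] = Field(
        default=None,
        ge=1,
        description="cells per spheroid; None = derived from packing geometry",
    )
    swelling: SwellingKinetics = Field(default_factory=SwellingKinetics)
    dox: DoxParams = Field(default_factory=DoxParams)
    imaging: ImagingParams = Field(default_factory=ImagingParams)
    n_frames: int = Field(default=8, ge=1)
    n_z: int = Field(default=1, ge=1, description="Z slices per timepoint")
    seed: int = Field(default=0, ge=0)

    @model_validator(mode="after")
    def _check_radii(self):
        radii = self.radii()
        if any(not r > 0 for r in radii):
            raise ValueError(f"base_radius_um entries must be > 0, got {radii}")
        if isinstance(self.base_radius_um, list) and len(radii) != self.n_spheroids:
            raise ValueError(
                f"base_radius_um lists one radius per spheroid: got {len(radii)} "
                f"for n_spheroids={self.n_spheroids}"
            )
        return self

    def radii(self) -> list[float]:
        """Base radius per spheroid (scalar broadcast to n_spheroids)."""
        if isinstance(self.base_radius_um, list):
            return list(self.base_radius_um)
        return [float(self.base_radius_um)] * self.n_spheroids


class SegmentationParams(_Model):
    """Tunable knobs of the spheroid and cell segmentation algorithms."""

    variance_window_px: int = Field(default=15, ge=3, description="local-variance window")
    closing_radius_px: int = Field(default=5, ge=1)
    min_object_area_px: int = Field(default=400, ge=1)
    object_policy: str = Field(default="largest", pattern="^(largest|all)$")
    gate_um: float = Field(
        default=30.0, gt=0, description="max centroid displacement per frame"
    )
    max_gap_frames: int = Field(default=2, ge=0)
    ridge_sigma_um: float = Field(default=1.0, gt=0)
    h_frac: float = Field(
        default=0.10, gt=0, lt=1, description="h-minima depth, fraction of dynamic range"
    )
    cell_area_bounds_um2: tuple[float, float] = Field(default=(20.0, 500.0))

    @field_validator("cell_area_bounds_um2")
    @classmethod
    def _check_bounds(cls, v):
        lo, hi = v
        if not 0 < lo < hi:
            raise ValueError(f"cell_area_bounds_um2 needs 0 < min < max, got {v}")
        return v


class AnalysisParams(_Model):
    """Swelling/uptake analysis settings."""

    n_cycles: int = Field(default=3, ge=1)
    peak_lag_min: float = Field(
        default=60.0,
        ge=0,
        description="peak search extends this far past the 0%-O2 phase",
    )
    peak_window: str = Field(default="zero_phase_plus_lag", pattern="^(zero_phase_plus_lag|full_cycle)$")
    target_depth_um: float = Field(default=40.0, ge=0)
    depth_bin_um: float = Field(default=2.0, gt=0)
    guard_depth_um: float = Field(
        default=10.0,
        ge=0,
        description="depth bins shallower than this are flagged as edge-biased",
    )
    background_subtract: bool = Field(default=True)


class RunConfig(_Model):
    """Top-level config file: one document drives simulate + analyze."""

    schedule: ScheduleConfig
    phantom: PhantomParams = Field(default_factory=PhantomParams)
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    analysis: AnalysisParams = Field(default_factory=AnalysisParams)
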