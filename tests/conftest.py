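"""Shared fixtures: small deterministic phantoms reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from spherox import OxygenSchedule, generate_phantom
from spherox.config import ImagingParams, PhantomParams, SwellingKinetics


@pytest.fixture(scope="session")
def cycling_schedule() -> OxygenSchedule:
    """The three-level 12 h cycling profile (2 h 0%, 6 h 3%, 4 h 10%)."""
    return OxygenSchedule([(120, 0.0), (360, 3.0), (240, 10.0)], repeat_count=3)


@pytest.fixture(scope="session")
def noise_free_swelling_phantom():
    """Noise-free brightfield time-lapse with programmed swelling."""
    schedule = OxygenSchedule([(60, 0.0), (120, 10.0)], repeat_count=3)
    params = PhantomParams(
        n_spheroids=1,
        base_radius_um=40.0,
        swelling=SwellingKinetics(s_eq={0.0: 1.08, 10.0: 1.0}, tau_min=20.0, s0=1.0),
        imaging=ImagingParams(
            fov_px=128, frame_interval_min=30.0, photon_scale=None, read_noise_sd=0.0
        ),
        n_frames=19,
        seed=21,
    )
    return generate_phantom(params, schedule, "brightfield") + (schedule,)


@pytest.fixture(scope="session")
def membrane_200():
    """High-SNR membrane-stain slice with exactly 200 ground-truth cells."""
    schedule = OxygenSchedule([(100, 20.0)])
    params = PhantomParams(
        n_spheroids=1,
        base_radius_um=90.0,
        n_cells=200,
        swelling=SwellingKinetics(s_eq={20.0: 1.0}, s0=1.0),
        imaging=ImagingParams(fov_px=224, photon_scale=2000.0, read_noise_sd=0.002),
        n_frames=1,
        seed=3,
    )
    return generate_phantom(params, schedule, "membrane")


@pytest.fixture(scope="session")
def dox_zstack():
    """Small noise-free doxorubicin Z-stack (sphere cross-sections)."""
    schedule = OxygenSchedule([(1000, 10.0)])
    params = PhantomParams(
        n_spheroids=1,
        base_radius_um=40.0,
        swelling=SwellingKinetics(s_eq={10.0: 1.0}, s0=1.0),
        imaging=ImagingParams(
            fov_px=112,
            frame_interval_min=300.0,
            z_spacing_um=4.0,
            photon_scale=None,
            read_noise_sd=0.0,
        ),
        n_frames=3,
        n_z=24,
        seed=9,
    )
    return generate_phantom(params, schedule, "dox")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
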