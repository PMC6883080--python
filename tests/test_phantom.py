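import math

import numpy as np
import pytest

from spherox import (
    DoxParams,
    OxygenSchedule,
    calibrate_swelling_amplitude,
    generate_phantom,
    normalize_trace,
    per_cycle_swelling,
    simulate_dox_field,
    simulate_swelling_trace,
)
from spherox.config import ImagingParams, PhantomParams, SwellingKinetics
from spherox.phantom import cvt_disk_points, dox_steady_state


class TestSwellingTrace:
    def test_constant_oxygen_is_a_fixed_point(self):
        sch = OxygenSchedule([(600, 10.0)])
        _, s = simulate_swelling_trace(sch, {10.0: 1.04}, 30.0, 600, 10.0)
        assert np.allclose(s, 1.04, rtol=0, atol=1e-15)

    def test_step_response_matches_closed_form(self):
        """A single o2 step relaxes as s_eq + (s0-s_eq)*exp(-t/tau)."""
        sch = OxygenSchedule([(600, 0.0)])
        tau, s0, seq = 37.0, 1.0, 1.1
        t, s = simulate_swelling_trace(sch, {0.0: seq}, tau, 600, 7.5, s0=s0)
        expected = seq + (s0 - seq) * np.exp(-t / tau)
        assert np.allclose(s, expected, rtol=1e-9)

    def test_long_plateaus_reach_equilibrium_area_ratio(self):
        """Plateaus >> tau: per-cycle area swelling -> (s_eq0/s_eq10)^2 - 1."""
        sch = OxygenSchedule([(300, 0.0), (300, 10.0)], repeat_count=3)
        s_eq = {0.0: 1.05, 10.0: 1.0}
        t, s = simulate_swelling_trace(sch, s_eq, 10.0, sch.total_min, 10.0, s0=1.0)
        trace = normalize_trace((s / s[0]) ** 2, t)
        summary = per_cycle_swelling(trace, sch, n_cycles=3, peak_lag_min=60.0)
        assert summary.mean_pct == pytest.approx(100 * (1.05**2 - 1), abs=0.01)

    def test_missing_s_eq_entry_is_a_configuration_error(self):
        sch = OxygenSchedule([(60, 0.0), (60, 3.0)])
        with pytest.raises(ValueError, match="3.0"):
            simulate_swelling_trace(sch, {0.0: 1.05}, 30.0, 120, 30.0)

    def test_mid_phase_sampling_grid_is_still_exact(self):
        """A grid not aligned with phase boundaries sub-steps exactly."""
        sch = OxygenSchedule([(100, 0.0), (100, 10.0)])
        s_eq = {0.0: 1.1, 10.0: 1.0}
        tau = 25.0
        t, s = simulate_swelling_trace(sch, s_eq, tau, 200, 33.0, s0=1.0)
        # closed form pieced across the boundary at t=100
        def exact(ti):
            if ti <= 100:
                return 1.1 + (1.0 - 1.1) * math.exp(-ti / tau)
            s100 = 1.1 + (1.0 - 1.1) * math.exp(-100 / tau)
            return 1.0 + (s100 - 1.0) * math.exp(-(ti - 100) / tau)
        assert np.allclose(s, [exact(ti) for ti in t], rtol=1e-9)


class TestCalibration:
    @pytest.mark.parametrize("target", [5.0, 10.0, 15.0, 20.0])
    def test_recovers_programmed_amplitude(self, target):
        sch = OxygenSchedule([(120, 0.0), (360, 3.0), (240, 10.0)], repeat_count=3)
        s_eq = calibrate_swelling_amplitude(target, sch, dt_min=30.0)
        t, s = simulate_swelling_trace(sch, s_eq, 30.0, sch.total_min, 30.0, s0=1.0)
        trace = normalize_trace((s / s[0]) ** 2, t)
        summary = per_cycle_swelling(trace, sch, n_cycles=3)
        assert summary.mean_pct == pytest.approx(target, abs=1e-6)


class TestDoxField:
    def test_initial_condition_is_zero(self):
        r, C = simulate_dox_field(50.0, DoxParams(), [0.0])
        assert np.all(C == 0)

    def test_pure_diffusion_equilibrates_to_bath(self):
        r, C = simulate_dox_field(
            50.0, DoxParams(k_uptake_per_min=0.0), [0.0, 20000.0], n_r=101
        )
        assert np.max(np.abs(C[-1] - 1.0)) < 1e-3

    def test_steady_state_matches_analytic_sphere_solution(self):
        """C(r) -> (R/r) sinh(r sqrt(k/D)) / sinh(R sqrt(k/D))."""
        dp = DoxParams(D_um2_per_min=60.0, k_uptake_per_min=0.02)
        r, C = simulate_dox_field(75.0, dp, [0.0, 6000.0], n_r=401)
        exact = dox_steady_state(75.0, dp.D_um2_per_min, dp.k_uptake_per_min, r)
        assert np.max(np.abs(C[-1] - exact) / exact) < 0.01

    def test_monotone_in_time_and_radius(self):
        dp = DoxParams(D_um2_per_min=30.0, k_uptake_per_min=0.05)
        r, C = simulate_dox_field(60.0, dp, [0, 10, 30, 90, 270], n_r=151)
        assert np.all(np.diff(C, axis=0) >= -1e-12)  # non-decreasing in t
        assert np.all(np.diff(C[1:], axis=1) >= -1e-12)  # edge-bright in r

    def test_grid_refinement_converges(self):
        """Halving dr and dt changes the profile by < 0.5%."""
        dp = DoxParams(D_um2_per_min=60.0, k_uptake_per_min=0.02)
        r1, C1 = simulate_dox_field(60.0, dp, [60.0], n_r=101, dt_min=0.5)
        r2, C2 = simulate_dox_field(60.0, dp, [60.0], n_r=201, dt_min=0.25)
        on_coarse = np.interp(r1, r2, C2[-1])
        denom = np.maximum(on_coarse, 1e-3)
        assert np.max(np.abs(C1[-1] - on_coarse) / denom) < 0.005

    @pytest.mark.parametrize("D,k", [(-1.0, 0.02), (0.0, 0.02), (60.0, -0.1)])
    def test_invalid_transport_parameters(self, D, k):
        # model_construct bypasses pydantic so the function's own guard fires
        dp = DoxParams.model_construct(
            D_um2_per_min=D, k_uptake_per_min=k, heterogeneity_cv=0.3, scatter_length_um=80.0
        )
        with pytest.raises(ValueError):
            simulate_dox_field(50.0, dp, [0.0])


class TestGeneratePhantom:
    def test_unknown_modality_rejected(self):
        params = PhantomParams(n_frames=1)
        sch = OxygenSchedule([(60, 10.0)])
        with pytest.raises(ValueError, match="modality"):
            generate_phantom(
                params.model_copy(update={"swelling": SwellingKinetics(s_eq={10.0: 1.0})}),
                sch,
                "confocal",
            )

    def test_oversized_spheroid_error_names_offender(self):
        sch = OxygenSchedule([(60, 10.0)])
        params = PhantomParams(
            base_radius_um=200.0,
            swelling=SwellingKinetics(s_eq={10.0: 1.0}),
            imaging=ImagingParams(fov_px=128),
            n_frames=1,
        )
        with pytest.raises(ValueError, match="spheroid 0"):
            generate_phantom(params, sch, "brightfield")

    def test_same_seed_bit_identical_different_seed_differs(self):
        sch = OxygenSchedule([(120, 10.0)])
        def make(seed):
            params = PhantomParams(
                base_radius_um=30.0,
                swelling=SwellingKinetics(s_eq={10.0: 1.0}),
                imaging=ImagingParams(fov_px=96),
                n_frames=2,
                seed=seed,
            )
            return generate_phantom(params, sch, "brightfield")[0].data
        a, b, c = make(5), make(5), make(6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_ground_truth_area_is_scaled_disk_area(
        self, noise_free_swelling_phantom
    ):
        stack, gt, schedule = noise_free_swelling_phantom
        r0 = gt.base_radius_um[0]
        assert np.allclose(gt.true_area_um2[0], np.pi * (gt.s[0] * r0) ** 2)
        # area ratio between any two frames equals the squared scale ratio
        ratio = gt.true_area_um2[0, 5] / gt.true_area_um2[0, 0]
        assert ratio == pytest.approx((gt.s[0, 5] / gt.s[0, 0]) ** 2, rel=1e-12)

    def test_noise_free_render_matches_analytic_disk(
        self, noise_free_swelling_phantom
    ):
        """Thresholding the noise-free brightfield render recovers the true
        disk with Dice >= 0.98 and area within 1%."""
        stack, gt, schedule = noise_free_swelling_phantom
        for frame in (0, stack.n_frames - 1):
            rendered = stack.frame(frame) < 0.8  # object is dark on bright bg
            true = gt.disk_mask(frame, stack.shape_yx)
            dice = 2 * (rendered & true).sum() / (rendered.sum() + true.sum())
            assert dice >= 0.98
            assert rendered.sum() == pytest.approx(true.sum(), rel=0.01)

    def test_membrane_ground_truth_has_requested_cells(self, membrane_200):
        stack, gt = membrane_200
        labels = gt.label_maps[0]
        assert len(np.unique(labels[labels > 0])) == 200
        assert len(gt.cell_areas_um2[0]) == 200
        # label map partitions the rendered disk: no unlabeled interior pixels
        disk = gt.disk_mask(0, stack.shape_yx)
        assert np.all(labels[disk] > 0)

    def test_confinement_gain_inflates_area_change_only_without_shell(self):
        sch = OxygenSchedule([(120, 0.0)])
        kin = SwellingKinetics(s_eq={0.0: 1.05}, tau_min=30.0, s0=1.0)
        img = ImagingParams(fov_px=112, frame_interval_min=60.0, photon_scale=None, read_noise_sd=0.0)
        base = PhantomParams(base_radius_um=30.0, swelling=kin, imaging=img, n_frames=3)
        _, plain = generate_phantom(base, sch, "brightfield")
        _, inflated = generate_phantom(
            base.model_copy(update={"confinement_gain": 2.0}), sch, "brightfield"
        )
        assert np.allclose(inflated.s[0] - 1.0, 2.0 * (plain.s[0] - 1.0))
        _, shelled = generate_phantom(
            base.model_copy(update={"confinement_gain": 2.0, "has_shell": True}),
            sch,
            "brightfield",
        )
        assert np.allclose(shelled.s[0], plain.s[0])  # shells are not compacted

    def test_cell_areas_scale_with_s_squared(self, noise_free_swelling_phantom):
        stack, gt, schedule = noise_free_swelling_phantom
        a0 = gt.cell_areas_at(0)
        a5 = gt.cell_areas_at(5)
        assert np.allclose(a5 / a0, gt.s[0, 5] ** 2 / gt.s[0, 0] ** 2)


class TestCVT:
    def test_requested_count_and_containment(self, rng):
        pts = cvt_disk_points(50, 30.0, rng)
        assert pts.shape == (50, 2)
        assert np.all(np.hypot(pts[:, 0], pts[:, 1]) <= 30.0)

    def test_lloyd_relaxation_tightens_area_spread(self, rng):
        """Relaxed tessellations are more uniform than random ones."""
        from scipy.spatial import cKDTree

        def area_cv(n_iter):
            pts = cvt_disk_points(80, 40.0, np.random.default_rng(4), n_iter=n_iter)
            ax = np.linspace(-40, 40, 160)
            xx, yy = np.meshgrid(ax, ax)
            inside = xx**2 + yy**2 <= 1600
            _, lab = cKDTree(pts).query(np.column_stack([xx[inside], yy[inside]]))
            counts = np.bincount(lab, minlength=80)
            return counts.std() / counts.mean()

        assert area_cv(10) < area_cv(0)
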