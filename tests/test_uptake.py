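import numpy as np
import pytest
from scipy.ndimage import binary_dilation, distance_transform_edt

from spherox import (
    ImageStack,
    accumulation_timecourse,
    mean_intensity_in_mask,
    penetration_profile,
    select_representative_slice,
)


def _disk(shape, center, radius):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _zstack_with_surface(n_z, z_spacing, surface_slice, shape=(48, 48)):
    """Bright disk appearing from ``surface_slice`` downward."""
    data = np.zeros((1, n_z, *shape), dtype=np.float32)
    for z in range(surface_slice, n_z):
        data[0, z][_disk(shape, (24, 24), 18)] = 1.0
    return ImageStack(
        data, pixel_size_um=1.0, timestamps_min=[0.0], z_spacing_um=z_spacing
    )


class TestRepresentativeSlice:
    def test_target_40um_at_4um_spacing(self):
        stack = _zstack_with_surface(n_z=15, z_spacing=4.0, surface_slice=0)
        assert select_representative_slice(stack, 40.0) == 10

    def test_target_zero_returns_surface(self):
        stack = _zstack_with_surface(n_z=8, z_spacing=4.0, surface_slice=2)
        assert select_representative_slice(stack, 0.0) == 2

    def test_nearest_rule_at_3um_spacing(self):
        # 40/3 = 13.33 slices: 13 (39 um) is nearer than 14 (42 um)
        stack = _zstack_with_surface(n_z=20, z_spacing=3.0, surface_slice=0)
        assert select_representative_slice(stack, 40.0) == 13

    def test_surface_offset_added(self):
        stack = _zstack_with_surface(n_z=18, z_spacing=4.0, surface_slice=3)
        assert select_representative_slice(stack, 40.0) == 13

    def test_too_shallow_stack_reports_available_depth(self):
        stack = _zstack_with_surface(n_z=6, z_spacing=4.0, surface_slice=0)
        with pytest.raises(ValueError, match="20.0 um"):
            select_representative_slice(stack, 40.0)


class TestMeanIntensity:
    def test_uniform_slice_returns_value(self):
        mask = _disk((32, 32), (16, 16), 10)
        assert mean_intensity_in_mask(np.full((32, 32), 3.25), mask) == 3.25

    def test_hand_arithmetic_top_row(self):
        sl = np.arange(1, 10, dtype=float).reshape(3, 3)
        mask = np.zeros((3, 3), bool)
        mask[0] = True
        assert mean_intensity_in_mask(sl, mask) == 2.0

    def test_matches_per_pixel_loop_oracle(self, rng):
        sl = rng.uniform(0, 10, (40, 40))
        mask = rng.uniform(size=(40, 40)) < 0.3
        mask[5, 5] = True
        total, n = 0.0, 0
        for i in range(40):
            for j in range(40):
                if mask[i, j]:
                    total += sl[i, j]
                    n += 1
        assert mean_intensity_in_mask(sl, mask) == pytest.approx(total / n, rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_intensity_in_mask(np.zeros((4, 4)), np.zeros((4, 4), bool))


class TestPenetrationProfile:
    def test_uniform_slice_gives_flat_profile(self):
        mask = _disk((64, 64), (32, 32), 25)
        prof = penetration_profile(np.full((64, 64), 2.0), mask, 2.0)
        assert np.allclose(prof.mean_intensity[prof.n_pixels > 0], 2.0)

    def test_radial_ramp_bin_means_equal_bin_centres(self):
        """I(r) = depth-to-edge: each bin's mean sits near its centre."""
        mask = _disk((96, 96), (48, 48), 40)
        depth = distance_transform_edt(mask)  # pixel size 1 um
        prof = penetration_profile(depth, mask, 4.0)
        sel = prof.n_pixels > 30
        assert np.all(
            np.abs(prof.mean_intensity[sel] - prof.bin_centers_um[sel]) <= 2.0
        )

    def test_matches_brute_force_binning_exactly(self, rng):
        sl = rng.uniform(0, 5, (48, 48))
        mask = _disk((48, 48), (24, 24), 17)
        w, p = 3.0, 0.8
        prof = penetration_profile(sl, mask, w, pixel_size_um=p)
        depth = distance_transform_edt(mask) * p
        n_bins = len(prof.n_pixels)
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins, int)
        for i in range(48):
            for j in range(48):
                if mask[i, j]:
                    b = min(int(depth[i, j] / w), n_bins - 1)
                    sums[b] += sl[i, j]
                    counts[b] += 1
        assert np.array_equal(prof.n_pixels, counts)
        nz = counts > 0
        assert np.allclose(prof.mean_intensity[nz], sums[nz] / counts[nz], rtol=1e-14)

    def test_rotation_invariance(self, rng):
        sl = rng.uniform(0, 5, (48, 48))
        mask = _disk((48, 48), (20, 28), 15)
        a = penetration_profile(sl, mask, 2.0)
        b = penetration_profile(np.rot90(sl), np.rot90(mask), 2.0)
        assert np.array_equal(a.n_pixels, b.n_pixels)
        nz = a.n_pixels > 0
        assert np.allclose(a.mean_intensity[nz], b.mean_intensity[nz])

    def test_dilated_mask_shows_rising_limb_and_guard_flags(self, dox_zstack):
        """Over-segmented masks put background in the shallow bins, so the
        profile rises over the first ~10 um and those bins are flagged."""
        stack, gt = dox_zstack
        rep = stack.n_z // 2
        frame = stack.frame(stack.n_frames - 1, rep)
        true_mask = gt.disk_mask(stack.n_frames - 1, stack.shape_yx)
        fat = binary_dilation(true_mask, iterations=10)
        prof = penetration_profile(frame, fat, 2.0, guard_depth_um=10.0)
        vals = prof.mean_intensity
        assert np.nanargmax(vals[:10]) > 2  # rising limb in the shallow bins
        assert prof.guard_flags[:5].all()
        assert not prof.guard_flags[6:].any()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            penetration_profile(np.zeros((8, 8)), np.zeros((8, 8), bool), 2.0)


class TestAccumulation:
    def _masks_from_truth(self, stack, gt):
        masks = []
        for t in range(stack.n_frames):
            per_z = []
            for z, z_um in enumerate(gt.slice_z_um):
                r_eff = gt.s[0, t] * gt.base_radius_um[0]
                if abs(z_um) >= r_eff:
                    per_z.append(None)
                    continue
                r_sl = np.sqrt(r_eff**2 - z_um**2) / stack.pixel_size_um
                m = _disk(stack.shape_yx, tuple(gt.centers_px[0]), r_sl)
                per_z.append(m if m.any() else None)
            masks.append(per_z)
        return masks

    def test_stack_mean_is_pixel_weighted_slice_mean(self, dox_zstack):
        stack, gt = dox_zstack
        masks = self._masks_from_truth(stack, gt)
        df = accumulation_timecourse(
            stack, masks, condition="c", background_subtract=False
        )
        t = stack.n_frames - 1
        total, n = 0.0, 0
        for z in range(stack.n_z):
            m = masks[t][z]
            if m is None:
                continue
            total += stack.frame(t, z).astype(np.float64)[m].sum()
            n += m.sum()
        assert df["stack_mean"].iloc[t] == pytest.approx(total / n, rel=1e-12)

    def test_series_nondecreasing_for_monotone_field(self, dox_zstack):
        """Accumulation inherits the monotonicity of the dox field."""
        stack, gt = dox_zstack
        masks = self._masks_from_truth(stack, gt)
        df = accumulation_timecourse(
            stack, masks, condition="c", background_subtract=False
        )
        means = df["stack_mean"].to_numpy()
        assert np.all(np.diff(means) > -1e-9)
        # pre-drug frame is essentially background only
        assert means[0] < 0.1 * means[-1]

    def test_missing_segmentation_flagged(self, dox_zstack):
        stack, gt = dox_zstack
        masks = self._masks_from_truth(stack, gt)
        masks[1] = [None] * stack.n_z
        df = accumulation_timecourse(stack, masks, condition="c")
        assert df["missing"].tolist() == [False, True, False]
        assert np.isnan(df["stack_mean"].iloc[1])
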