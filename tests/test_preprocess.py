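"""Volume conditioning: background, registration, COM alignment, resampling."""

import numpy as np
import pytest

from waveonset.preprocess import (
    VolumeSeries,
    align_by_mask_com,
    register_recursive,
    resample_isotropic,
    subsample_xy,
    subtract_temporal_background,
)


def _series(data, spacing=(1.0, 1.0, 1.0), dt=10.0):
    return VolumeSeries(data=np.asarray(data, dtype=np.float32), voxel_spacing=spacing, frame_interval=dt)


class TestBackgroundSubtraction:
    BOX = ((0, 4), (0, 4), (0, 4))

    def test_box_mean_pinned_at_offset(self):
        rng = np.random.default_rng(0)
        data = rng.uniform(400, 600, size=(2, 10, 10, 10))
        vol = _series(data)
        out = subtract_temporal_background(vol, self.BOX, offset=1000.0)
        for t in range(2):
            box = out.data[t][0:4, 0:4, 0:4]
            assert box.mean() == pytest.approx(1000.0, abs=1e-3)

    def test_idempotent_once_pinned(self):
        rng = np.random.default_rng(1)
        vol = _series(rng.uniform(400, 600, size=(2, 10, 10, 10)))
        once = subtract_temporal_background(vol, self.BOX)
        twice = subtract_temporal_background(once, self.BOX)
        assert np.allclose(once.data, twice.data, atol=1e-3)

    def test_frame_offsets_removed(self):
        """Frames differing by a constant become equal after correction."""
        base = np.random.default_rng(2).uniform(100, 300, size=(8, 8, 8))
        vol = _series(np.stack([base + 500.0, base + 700.0]))
        out = subtract_temporal_background(vol, self.BOX)
        assert np.allclose(out.data[0], out.data[1], atol=1e-3)

    def test_box_outside_bounds_errors(self):
        vol = _series(np.zeros((1, 5, 5, 5)))
        with pytest.raises(IndexError, match="outside volume bounds"):
            subtract_temporal_background(vol, ((0, 10), (0, 3), (0, 3)))


def _blob_series(shifts, shape=(24, 24, 24), fill=1000.0):
    """A bright off-centre cube translated by integer shifts per frame."""
    frames = []
    for s in shifts:
        f = np.full(shape, fill, dtype=np.float32)
        z, y, x = 6 + s[0], 6 + s[1], 6 + s[2]
        f[z : z + 5, y : y + 5, x : x + 5] = 3000.0
        frames.append(f)
    return _series(np.stack(frames))


class TestRegistration:
    def test_identity_estimator_is_noop(self):
        vol = _blob_series([(0, 0, 0), (2, 0, 0), (4, 0, 0)])
        out, shifts = register_recursive(vol, pairwise_estimator=lambda f, m: (0, 0, 0))
        assert np.array_equal(out.data, vol.data)
        assert shifts == [(0, 0, 0)] * 3

    @pytest.mark.parametrize("reference_index", [0, 2, 4])
    def test_integer_shift_phantom_recovered_exactly(self, reference_index):
        """A +2-voxel-per-frame drift is undone frame-exactly from any reference."""
        vol = _blob_series([(0, 0, 2 * k) for k in range(5)])
        out, shifts = register_recursive(vol, reference_index=reference_index, fill_value=1000.0)
        ref = vol.data[reference_index]
        for t in range(5):
            assert np.array_equal(out.data[t], ref), f"frame {t} differs"
        # both directions produce transforms when the reference is interior
        if reference_index == 2:
            assert any(s != (0, 0, 0) for s in shifts[:2])
            assert any(s != (0, 0, 0) for s in shifts[3:])


class TestComAlignment:
    def test_symmetric_cube_maps_to_center(self):
        data = np.full((2, 21, 21, 21), 1000.0, dtype=np.float32)
        data[:, 2:7, 4:9, 6:11] = 2000.0  # cube centred at (4, 6, 8)
        vol = _series(data)
        out, res = align_by_mask_com(vol, threshold=1030.0)
        assert res.translation_vox == (6, 4, 2)
        assert res.rotation_deg == (0.0, 0.0, 0.0)
        # re-derive the COM of the aligned masks: should sit at the centre
        summed = sum((out.data[t] > 1030.0).astype(float) for t in range(2))
        from scipy.ndimage import center_of_mass

        com = np.array(center_of_mass(summed))
        assert np.abs(com - 10.0).max() <= 0.5

    def test_empty_mask_reports_threshold(self):
        vol = _series(np.zeros((1, 8, 8, 8)))
        with pytest.raises(ValueError, match="1030"):
            align_by_mask_com(vol, threshold=1030.0)

    def test_summed_mask_com_is_weighted_mean_of_frames(self):
        """Brute-force voxel-sum oracle for the two-frame summed-mask COM."""
        data = np.zeros((2, 16, 16, 16), dtype=np.float32)
        data[0, 2:4, 2:4, 2:4] = 2000.0
        data[1, 10:14, 10:14, 10:14] = 2000.0
        vol = _series(data)
        _, res = align_by_mask_com(vol, threshold=1030.0)
        # oracle: explicit sum over voxels of the summed mask
        summed = (data[0] > 1030).astype(float) + (data[1] > 1030).astype(float)
        idx = np.argwhere(summed > 0)
        w = summed[tuple(idx.T)]
        oracle = (idx * w[:, None]).sum(axis=0) / w.sum()
        assert np.allclose(res.com_vox, oracle, atol=1e-9)

    def test_landmark_transform_follows_volume(self):
        data = np.full((1, 21, 21, 21), 0.0, dtype=np.float32)
        data[0, 2:7, 4:9, 6:11] = 2000.0
        vol = _series(data)
        _, res = align_by_mask_com(vol, threshold=1030.0)
        moved = res.apply_to_points(np.array([4.0, 6.0, 8.0]))
        assert np.allclose(moved, [10.0, 10.0, 10.0])


class TestResampling:
    def test_constant_volume_unchanged(self):
        vol = _series(np.full((2, 10, 6, 6), 7.0), spacing=(3.59, 1.0, 1.0))
        out = resample_isotropic(vol, 3.59)
        assert np.allclose(out.data, 7.0)
        assert out.voxel_spacing[0] == pytest.approx(1.0)

    def test_linear_ramp_interpolates_exactly(self):
        nz = 11
        ramp = np.arange(nz, dtype=np.float32)[None, :, None, None] * np.ones((1, nz, 4, 4), np.float32)
        vol = _series(ramp, spacing=(2.0, 1.0, 1.0))
        out = resample_isotropic(vol, 2.0)
        new_nz = out.data.shape[1]
        expected = np.linspace(0.0, nz - 1.0, new_nz)
        assert np.allclose(out.data[0, :, 2, 2], expected, atol=1e-5)

    def test_subsample_factor_one_is_identity(self):
        vol = _series(np.random.default_rng(0).uniform(size=(1, 4, 8, 8)))
        out = subsample_xy(vol, 1)
        assert np.array_equal(out.data, vol.data)

    def test_subsample_block_mean_matches_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(size=(1, 2, 8, 8)).astype(np.float32)
        out = subsample_xy(_series(data), 2)
        oracle = data.reshape(1, 2, 4, 2, 4, 2).mean(axis=(3, 5))
        assert np.allclose(out.data, oracle, atol=1e-6)
        assert out.voxel_spacing[1] == pytest.approx(2.0)

    def test_subsample_constant_fractional_factor(self):
        vol = _series(np.full((1, 3, 30, 30), 5.0))
        out = subsample_xy(vol, 3.75)
        assert np.allclose(out.data, 5.0, atol=1e-5)
        assert out.data.shape[2] == 8

    def test_subsample_too_small_errors(self):
        vol = _series(np.zeros((1, 3, 6, 6)))
        with pytest.raises(ValueError, match="fewer than 2"):
            subsample_xy(vol, 4)
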