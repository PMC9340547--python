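"""LOI geometry: landmarks, surface path, kymograph sampling, profiles."""

import numpy as np
import pytest

from waveonset.loi import (
    Kymograph,
    LandmarkSet,
    build_surface_path,
    interpolate_landmarks,
    locate_intermediate_point,
    mip_kymograph,
    normalize_profile,
    sample_surface_kymograph,
    transverse_section,
)
from waveonset.preprocess import VolumeSeries


class TestLandmarkInterpolation:
    def _lm(self):
        return LandmarkSet(
            times=[0.0, 10.0, 30.0],
            origin=[[0, 0, 0], [10, 0, 0], [30, 0, 0]],
            left_distal=[[0, 5, 0], [0, 15, 0], [0, 35, 0]],
            right_distal=[[0, 0, 1], [0, 0, 2], [0, 0, 3]],
        )

    def test_midpoint_and_keyframe_and_clamp(self):
        fr = interpolate_landmarks(self._lm(), [-5.0, 0.0, 5.0, 10.0, 20.0, 99.0])
        assert np.allclose(fr.origin[2], [5, 0, 0])  # halfway between keyframes
        assert np.allclose(fr.origin[3], [10, 0, 0])  # exact at a keyframe
        assert np.allclose(fr.origin[0], [0, 0, 0])  # clamped before the span
        assert np.allclose(fr.origin[5], [30, 0, 0])  # clamped after the span
        assert np.allclose(fr.left_distal[4], [0, 25, 0])

    def test_empty_landmarks_rejected(self):
        with pytest.raises(ValueError):
            LandmarkSet(times=[], origin=np.zeros((0, 3)),
                        left_distal=np.zeros((0, 3)), right_distal=np.zeros((0, 3)))


class TestSurfacePath:
    def test_collinear_anchors_are_a_straight_segment(self):
        p = build_surface_path([0, 0, 0], [0, 0, 50], [0, 0, 100], n_segments=1000)
        assert p.total_length == pytest.approx(100.0, abs=1e-9)
        assert np.allclose(p.point_at_arc([25.0])[0], [0, 0, 25], atol=0.1)

    def test_quarter_circle_length_within_half_percent(self):
        r = 100.0
        ang = np.deg2rad([0.0, 45.0, 90.0])
        anchors = [[0.0, r * np.cos(a), r * np.sin(a)] for a in ang]
        p = build_surface_path(*anchors, n_segments=100_000)
        assert p.total_length == pytest.approx(np.pi * r / 2.0, rel=5e-3)

    def test_passes_through_anchors(self):
        anchors = np.array([[0, 100, 0], [20, 70, 71], [40, 0, 100]], float)
        p = build_surface_path(*anchors, n_segments=5000)
        ends = p.point_at_u([0.0, 1.0])
        assert np.allclose(ends[0], anchors[0], atol=1e-9)
        assert np.allclose(ends[1], anchors[2], atol=1e-9)
        mid_dist = np.linalg.norm(p.points - anchors[1], axis=1).min()
        assert mid_dist < 0.05  # intermediate anchor lies on the curve

    def test_chord_table_monotone_and_converged(self):
        """100k-chord total length agrees with the analytic curve length.

        The fitted curve through circle anchors is that circle, so its
        analytic length is radius × swept angle.
        """
        r = 80.0
        ang = np.deg2rad([10.0, 60.0, 120.0])
        anchors = [[5.0 * a, r * np.cos(a), r * np.sin(a)] for a in ang]
        p = build_surface_path(*anchors, n_segments=100_000)
        assert np.all(np.diff(p.cumulative_length) >= 0)
        assert p.total_length == pytest.approx(p.cumulative_length[-1])
        # analytic oracle: fine quadrature of the same parametric curve
        u = np.linspace(0, 1, 2_000_001)
        fine = np.sum(np.linalg.norm(np.diff(p.point_at_u(u), axis=0), axis=1))
        assert p.total_length == pytest.approx(fine, rel=1e-3)

    def test_integer_lookup_within_one_segment(self):
        p = build_surface_path([0, 0, 0], [0, 30, 50], [0, 0, 100], n_segments=50_000)
        d = np.arange(0.0, np.floor(p.total_length) + 0.5)
        u = p.u_at_arc(d)
        idx = np.searchsorted(p.u_table, u)
        got = p.cumulative_length[np.clip(idx, 0, p.n_segments)]
        seg_len = p.total_length / p.n_segments
        assert np.abs(got - d).max() <= 2 * seg_len + 1e-9

    def test_coincident_anchors_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            build_surface_path([0, 0, 0], [0, 0, 0], [0, 0, 10])


def _shell_volume(radius=20.0, shape=(64, 64, 64), inner=100.0, shell=1000.0, frames=1):
    """Spherical shell brighter than its surroundings, centred in the volume."""
    c = (np.array(shape) - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r = np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
    frame = np.where(np.abs(r - radius) <= 2.0, shell, inner).astype(np.float32)
    data = np.repeat(frame[None], frames, axis=0)
    return VolumeSeries(data=data, voxel_spacing=(1.0, 1.0, 1.0), frame_interval=10.0)


class TestIntermediatePoint:
    def test_finds_shell_radius(self):
        vol = _shell_volume(frames=2)
        c = vol.center_um()
        origin = np.tile([c[0] + 20.0, c[1], c[2]], (2, 1))
        distal = np.tile([c[0], c[1] + 20.0, c[2]], (2, 1))
        pts = locate_intermediate_point(vol, c, origin, distal)
        r = np.linalg.norm(pts - c, axis=1)
        assert np.abs(r - 20.0).max() <= 1.0

    def test_constant_ray_tie_breaks_to_com(self):
        vol = VolumeSeries(np.full((1, 16, 16, 16), 5.0, np.float32), (1, 1, 1), 10.0)
        c = vol.center_um()
        pts = locate_intermediate_point(vol, c, np.array([[7.5, 7.5, 14.0]]), np.array([[7.5, 14.0, 7.5]]))
        assert np.allclose(pts[0], c)  # first (closest) sample wins

    def test_linear_trajectory_survives_smoothing(self):
        """Maxima moving linearly in time are reproduced by the spline."""
        shape = (1, 40, 16, 16)
        T = 6
        data = np.zeros((T, 40, 16, 16), np.float32)
        for t in range(T):
            data[t, 10 + 2 * t, 8, 8] = 100.0
        vol = VolumeSeries(data, (1, 1, 1), 10.0)
        com = np.array([2.0, 8.0, 8.0])
        origin = np.tile([30.0, 4.0, 8.0], (T, 1))
        distal = np.tile([30.0, 12.0, 8.0], (T, 1))
        pts = locate_intermediate_point(vol, com, origin, distal)
        assert np.allclose(pts[:, 0], 10 + 2 * np.arange(T), atol=0.35)

    def test_degenerate_geometry_rejected(self):
        vol = _shell_volume()
        c = vol.center_um()
        with pytest.raises(ValueError, match="degenerate"):
            locate_intermediate_point(vol, c, np.array([[c[0], c[1] - 3, c[2]]]),
                                      np.array([[c[0], c[1] + 3, c[2]]]))


class TestSurfaceKymograph:
    def test_constant_shell_gives_constant_kymograph(self):
        vol = VolumeSeries(np.full((2, 32, 32, 32), 4.0, np.float32), (1, 1, 1), 10.0)
        path = build_surface_path([4, 16, 16], [10, 20, 16], [16, 24, 16], n_segments=2000)
        kym = sample_surface_kymograph(vol, [path, path], [path, path],
                                       smoothing_sigma_px=1.0, sphere_diameter_px=4.0)
        assert np.allclose(kym.data[kym.valid], 4.0, atol=1e-5)

    def test_symmetric_phantom_gives_symmetric_kymograph(self):
        vol = _shell_volume(frames=1)
        c = vol.center_um()
        left = build_surface_path(c + [20, 0, 0], c + [14.1, 14.1, 0], c + [0, 20, 0], n_segments=2000)
        right = build_surface_path(c + [20, 0, 0], c + [14.1, -14.1, 0], c + [0, -20, 0], n_segments=2000)
        kym = sample_surface_kymograph(vol, [left], [right], smoothing_sigma_px=1.0,
                                       sphere_diameter_px=4.0)
        m = kym.midline_row
        n = min(m, kym.n_rows - 1 - m)
        up = kym.data[m - n : m + 1][::-1, 0]
        down = kym.data[m : m + n + 1][:, 0]
        assert np.allclose(up, down, atol=1e-5)

    def test_arc_function_recovered_along_rows(self):
        """Intensity f(s) linear in arc distance appears as f(r·px) per row."""
        shape = (48, 48, 48)
        zz = np.arange(shape[0], dtype=np.float32)[:, None, None]
        data = np.broadcast_to(10.0 * zz, shape)[None].copy()
        vol = VolumeSeries(data, (1, 1, 1), 10.0)
        path = build_surface_path([10, 24, 24], [20, 24, 24], [30, 24, 24], n_segments=2000)
        kym = sample_surface_kymograph(vol, [path], [path], smoothing_sigma_px=2.0,
                                       sphere_diameter_px=6.0)
        rows = np.arange(kym.midline_row + 1)
        expect = 10.0 * (10.0 + rows)  # f(z) = 10 z along the straight path
        got = kym.data[kym.midline_row - rows, 0]
        assert np.abs(got - expect).max() < 1.0


class TestProjectionTools:
    def test_mip_kymograph_constant_image(self):
        vol = VolumeSeries(np.full((2, 8, 40, 40), 3.0, np.float32), (1, 1, 1), 10.0)
        path = build_surface_path([0, 5, 5], [0, 20, 22], [0, 35, 35], n_segments=2000)
        kym = mip_kymograph(vol, [path, path], projection_axis="z", corridor_um=5.0,
                            gaussian_sigma_um=2.0)
        assert np.allclose(kym.data[kym.valid], 3.0, atol=1e-5)

    def test_mip_corridor_too_wide_errors(self):
        vol = VolumeSeries(np.zeros((1, 4, 10, 10), np.float32), (1, 1, 1), 10.0)
        path = build_surface_path([0, 1, 1], [0, 5, 6], [0, 9, 9], n_segments=100)
        with pytest.raises(ValueError, match="corridor"):
            mip_kymograph(vol, [path], corridor_um=50.0)

    def test_transverse_section_shows_bright_voxel(self):
        data = np.zeros((1, 20, 12, 12), np.float32)
        data[0, 10, 3, 7] = 99.0
        vol = VolumeSeries(data, (1, 1, 1), 10.0)
        img = transverse_section(vol, 0, (0.0, 19.0), fraction=0.5, slab_um=6.0)
        assert img[3, 7] == 99.0

    def test_transverse_section_single_plane_is_slice(self):
        data = np.random.default_rng(0).uniform(size=(1, 10, 6, 6)).astype(np.float32)
        vol = VolumeSeries(data, (1, 1, 1), 10.0)
        img = transverse_section(vol, 0, (0.0, 9.0), fraction=0.5, slab_um=1.0)
        assert np.array_equal(img, data[0, 4:5].max(axis=0))

    def test_transverse_section_requires_annotation(self):
        vol = VolumeSeries(np.zeros((1, 8, 6, 6), np.float32), (1, 1, 1), 10.0)
        with pytest.raises(ValueError, match="annotation"):
            transverse_section(vol, 0, None)


class TestNormalizeProfile:
    def test_output_spans_unit_range(self):
        rng = np.random.default_rng(0)
        prof = np.sin(np.linspace(0, 3, 200)) + rng.normal(0, 0.05, 200) + 4.0
        out = normalize_profile(prof)
        assert out.max() == pytest.approx(1.0)
        assert out.min() == pytest.approx(0.0)

    def test_linear_profile_unchanged_by_lowess(self):
        prof = np.linspace(2.0, 7.0, 120)
        out = normalize_profile(prof, smooth=True, subtract_background=False, normalize_max=False)
        assert np.allclose(out, prof, atol=1e-6)

    def test_constant_profile_warns_and_zeroes(self):
        with pytest.warns(RuntimeWarning):
            out = normalize_profile(np.full(50, 3.0))
        assert np.allclose(out, 0.0)

    def test_raw_passthrough(self):
        prof = np.array([3.0, 1.0, 2.0, 5.0])
        out = normalize_profile(prof, smooth=False, subtract_background=False, normalize_max=False)
        assert np.array_equal(out, prof)


class TestKymographContainer:
    def test_invalid_cells_must_carry_fill(self):
        data = np.zeros((5, 3))
        valid = np.ones((5, 3), bool)
        valid[0, 0] = False
        with pytest.raises(ValueError, match="fill"):
            Kymograph(data=data, valid=valid, midline_row=2, spatial_pixel=1.0, dt=10.0, fill_value=7.0)

    def test_half_orders_midline_outward(self):
        data = np.arange(10, dtype=float).reshape(5, 2)
        kym = Kymograph(data=data, valid=np.ones((5, 2), bool), midline_row=2,
                        spatial_pixel=1.0, dt=10.0)
        left, _ = kym.half("left")
        right, _ = kym.half("right")
        assert left[0, 0] == data[2, 0] and left[-1, 0] == data[0, 0]
        assert right[0, 0] == data[2, 0] and right[-1, 0] == data[4, 0]
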