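"""Phantom generators: model fidelity, determinism, analytic ground truth."""

import numpy as np
import pytest

from waveonset.flow import CellTrack
from waveonset.synth import (
    PhantomSpec,
    generate_phantom_kymograph,
    generate_phantom_tracks,
    generate_phantom_volume,
)

SMALL_SHAPE = (96, 72, 72)
SMALL_GEOM = dict(shell_radius=50.0, shell_thickness=20.0, cylinder_height=50.0,
                  volume_shape=SMALL_SHAPE, n_frames=4)


class TestPhantomVolume:
    def test_degenerate_model_is_flat_background(self):
        spec = PhantomSpec(noise_sd=0.0, oscillation_amplitude=0.0, pulse_amplitude=0.0,
                           **SMALL_GEOM)
        vol, _, _ = generate_phantom_volume(spec)
        shell = vol.data[vol.data > 0]
        assert shell.size > 0
        assert np.allclose(shell, spec.background_level)

    def test_same_seed_bit_identical(self):
        spec = PhantomSpec(rng_seed=3, **SMALL_GEOM)
        v1, _, _ = generate_phantom_volume(spec)
        v2, _, _ = generate_phantom_volume(spec)
        assert np.array_equal(v1.data, v2.data)

    def test_uniform_period_matches_closed_form(self):
        """With no noise the shell equals bg + A(1+cos 2πt/P)/2 pointwise."""
        spec = PhantomSpec(noise_sd=0.0, proximal_period=150.0, distal_period=150.0,
                           pulse_amplitude=0.0, pulse_peak_time=-260.0, **SMALL_GEOM)
        vol, _, _ = generate_phantom_volume(spec)
        mask = vol.data[0] > 0
        for i, t in enumerate(vol.times):
            expected = spec.background_level + spec.oscillation_amplitude * 0.5 * (
                1.0 + np.cos(2.0 * np.pi * t / 150.0)
            )
            got = vol.data[i][mask]
            assert np.abs(got - expected).max() < 1e-3

    def test_oversized_shell_rejected(self):
        spec = PhantomSpec(volume_shape=(40, 40, 40), n_frames=3)
        with pytest.raises(ValueError, match="cannot contain"):
            generate_phantom_volume(spec)

    def test_landmarks_on_shell_surface(self):
        spec = PhantomSpec(noise_sd=0.0, **SMALL_GEOM)
        _, lm, _ = generate_phantom_volume(spec)
        # origin sits on the rim circle of mid-surface radius
        center_yx = np.array([(SMALL_SHAPE[1] - 1) / 2, (SMALL_SHAPE[2] - 1) / 2]) * spec.voxel_spacing
        r = np.hypot(lm.origin[0, 1] - center_yx[0], lm.origin[0, 2] - center_yx[1])
        assert r == pytest.approx(spec.shell_radius, abs=1e-6)


class TestPhantomKymograph:
    def test_uniform_static_rows_identical(self):
        spec = PhantomSpec(proximal_period=150.0, distal_period=150.0, growth_rate=0.0,
                           noise_sd=0.0, n_frames=30)
        kym, _ = generate_phantom_kymograph(spec)
        rows = kym.data[kym.valid.all(axis=1)]
        assert np.allclose(rows, rows[0])

    def test_fill_value_in_out_of_domain_cells(self):
        spec = PhantomSpec(growth_rate=0.2, n_frames=40)
        kym, _ = generate_phantom_kymograph(spec)
        assert (~kym.valid).any()
        assert np.all(kym.data[~kym.valid] == 1067.0)

    def test_extreme_row_phase_difference_matches_formula(self):
        """Δφ between origin and distal end equals 2πt(1/P_p − 1/P_d).

        The generator's analytic q is cross-checked against numerical
        integration of the instantaneous frequency difference.
        """
        spec = PhantomSpec(proximal_period=130.0, distal_period=150.0, growth_rate=0.0,
                           noise_sd=0.0, pulse_peak_time=-260.0, pulse_amplitude=0.0)
        _, gt = generate_phantom_kymograph(spec)
        t = 390.0
        delta = gt.phase(0.0, t) - gt.phase(gt.arc_length_initial, t)
        expected = 2.0 * np.pi * t * (1.0 / 130.0 - 1.0 / 150.0)
        assert delta == pytest.approx(expected, rel=1e-12)
        # independent oracle: integrate dφ/dt = 2π/P at both ends
        tt = np.linspace(0.0, t, 20001)
        num = np.trapezoid(2 * np.pi / gt.period_at(0.0) * np.ones_like(tt), tt) - np.trapezoid(
            2 * np.pi / gt.period_at(gt.arc_length_initial) * np.ones_like(tt), tt
        )
        assert delta == pytest.approx(num, rel=1e-6)
        assert gt.q_analytic(t) == pytest.approx(expected / (2 * np.pi), rel=1e-12)

    def test_phase_zero_everywhere_at_onset(self):
        _, gt = generate_phantom_kymograph(PhantomSpec())
        s = np.linspace(0.0, 400.0, 17)
        assert np.allclose(gt.phase(s, 0.0), 0.0)
        assert gt.q_analytic(0.0) == 0.0

    def test_growth_exceeding_rows_rejected(self):
        spec = PhantomSpec(growth_rate=1.0, n_frames=50)
        with pytest.raises(ValueError, match="rows"):
            generate_phantom_kymograph(spec, n_rows=2 * int(spec.initial_arc_length / spec.voxel_spacing) + 1)

    def test_seed_determinism(self):
        spec = PhantomSpec(rng_seed=11, n_frames=20)
        k1, _ = generate_phantom_kymograph(spec)
        k2, _ = generate_phantom_kymograph(spec)
        assert np.array_equal(k1.data, k2.data)


class TestPhantomTracks:
    def test_zero_speed_zero_jitter_is_stationary(self):
        spec = PhantomSpec(advection_speed=0.0, advection_speed_spread=0.0,
                           track_jitter_sd=0.0, n_tracks=5, n_frames=20)
        tracks, _ = generate_phantom_tracks(spec)
        for tr in tracks:
            assert np.allclose(tr.positions, tr.positions[0])

    def test_jitter_free_speed_matches_ground_truth(self):
        """Finite differences of a jitter-free track recover its true speed."""
        spec = PhantomSpec(track_jitter_sd=0.0, n_tracks=10, n_frames=30,
                           advection_speed_spread=0.0, growth_rate=0.0)
        # keep tracks on the straight (cylinder) part of the meridian, where
        # chord length and arc length coincide exactly
        tracks, gt = generate_phantom_tracks(spec, seed_arc_range=(5.0, 30.0))
        for tr in tracks:
            step = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
            speed = step / tr.dt
            assert np.abs(speed - gt.track_speeds[tr.track_id]).max() < 1e-9

    def test_default_speeds_span_reported_motility_range(self):
        spec = PhantomSpec(n_tracks=200, n_frames=5, rng_seed=5)
        _, gt = generate_phantom_tracks(spec)
        speeds = np.array(list(gt.track_speeds.values()))
        assert speeds.min() >= 0.1 - 1e-9
        assert speeds.max() <= 0.3 + 1e-9
        assert np.ptp(speeds) > 0.1  # actually spread over the range

    def test_seed_determinism(self):
        spec = PhantomSpec(n_tracks=8, n_frames=10, rng_seed=2)
        t1, _ = generate_phantom_tracks(spec)
        t2, _ = generate_phantom_tracks(spec)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.positions, b.positions)


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(noise_sd=-1.0),
            dict(frame_interval_dt=0.0),
            dict(shell_thickness=200.0),
            dict(n_frames=1),
            dict(proximal_period=50.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs).validate()
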