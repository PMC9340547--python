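"""Phantom embryos with known ground truth.

The generators emulate the statistical structure the analysis chain
assumes, at three levels of fidelity:

* :func:`generate_phantom_volume` renders a 3D+t "egg cylinder" — a
  hemispherical cap capped cylinder shell — expressing an oscillatory
  reporter whose period varies linearly with arc distance from the
  proximal wave origin on the cylinder rim, preceded by a quasi-synchronous
  Gaussian "pulse" in time, on top of a constant tissue background with
  additive Gaussian noise.  Landmark keyframes (origin, left/right distal
  ends) are emitted alongside.
* :func:`generate_phantom_kymograph` renders the same 1D intensity model
  straight into a midline-centred kymograph, bypassing 3D rendering.
* :func:`generate_phantom_tracks` seeds cell tracks near the origin and
  advects them along the shell surface away from it, with positional
  jitter, emulating the slow proportional tissue flow of the gastrulating
  mesoderm.

Every generator is deterministic given the spec (one seeded random stream
per artifact, so stages can be regenerated independently), and returns a
:class:`GroundTruth` carrying the analytic phase field, wave number and
landmark/velocity truths used by the recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .flow import CellTrack
from .loi import Kymograph, LandmarkSet, SurfacePath, build_surface_path
from .preprocess import VolumeSeries

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom_volume",
    "generate_phantom_kymograph",
    "generate_phantom_tracks",
    "reference_paths",
    "PULSE_TO_ONSET_MIN",
]

#: Interval between the pulse peak and the first visible wave (min).
PULSE_TO_ONSET_MIN = 260.0

# per-artifact random sub-streams
_STREAM_VOLUME = 1
_STREAM_KYMOGRAPH = 2
_STREAM_TRACKS = 3


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the phantom embryo.

    Times are minutes, lengths micrometres, intensities detector counts.
    The oscillation period varies linearly with arc distance ``s`` from the
    wave origin, from ``proximal_period`` at s = 0 to ``distal_period`` at
    the initial arc length, and stays at ``distal_period`` beyond it.
    Oscillations start synchronously (phase 0 everywhere)
    ``PULSE_TO_ONSET_MIN`` after the pulse peak.
    """

    proximal_period: float = 133.0
    distal_period: float = 153.0
    pulse_peak_time: float = 100.0
    pulse_width: float = 75.0
    pulse_amplitude: float = 300.0
    oscillation_amplitude: float = 300.0
    background_level: float = 200.0
    exterior_level: float = 0.0
    noise_sd: float = 20.0
    shell_radius: float = 100.0
    shell_thickness: float = 30.0
    cylinder_height: float = 120.0
    initial_arc_length: float = 330.0
    growth_rate: float = 0.1
    advection_speed: float = 0.2
    advection_speed_spread: float = 0.1
    track_jitter_sd: float = 0.5
    n_tracks: int = 60
    distal_cap_angle_deg: float = 80.0
    distal_azimuth_deg: float = 12.0
    voxel_spacing: float = 2.088
    frame_interval_dt: float = 10.0
    n_frames: int = 121
    volume_shape: tuple[int, int, int] = (160, 128, 128)
    rng_seed: int = 0
    period_bounds: tuple[float, float] = (100.0, 220.0)

    def validate(self) -> None:
        lo, hi = self.period_bounds
        for name in ("proximal_period", "distal_period"):
            p = getattr(self, name)
            if not lo <= p <= hi:
                raise ValueError(f"{name}={p} outside configured bounds [{lo}, {hi}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.frame_interval_dt <= 0:
            raise ValueError("frame interval must be positive")
        if not 0 < self.shell_thickness < self.shell_radius:
            raise ValueError("shell thickness must be positive and below the shell radius")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if self.initial_arc_length <= 0 or self.voxel_spacing <= 0:
            raise ValueError("arc length and voxel spacing must be positive")
        if self.growth_rate < 0 or self.advection_speed < 0:
            raise ValueError("growth and advection rates must be non-negative")

    @property
    def onset_time(self) -> float:
        """Absolute time at which oscillations start (min)."""
        return self.pulse_peak_time + PULSE_TO_ONSET_MIN

    @property
    def times(self) -> np.ndarray:
        return self.frame_interval_dt * np.arange(self.n_frames)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["volume_shape"] = list(self.volume_shape)
        d["period_bounds"] = list(self.period_bounds)
        return d


@dataclass
class GroundTruth:
    """Analytic truths of a phantom, for recovery tests.

    ``phase(s, t)`` takes arc distance s (μm) and time since oscillation
    onset t (min) and returns 2π·t / P(s); ``q_analytic(t)`` the wave number
    accumulated between the origin and the initial arc end,
    t·(1/P_prox − 1/P_dist).
    """

    spec: PhantomSpec
    arc_length_initial: float
    onset_time: float
    landmarks: LandmarkSet | None = None
    track_speeds: dict[int, float] = field(default_factory=dict)

    def period_at(self, s) -> np.ndarray:
        frac = np.clip(np.asarray(s, dtype=float) / self.arc_length_initial, 0.0, 1.0)
        return self.spec.proximal_period + frac * (self.spec.distal_period - self.spec.proximal_period)

    def phase(self, s, t_since_onset) -> np.ndarray:
        return 2.0 * np.pi * np.asarray(t_since_onset, dtype=float) / self.period_at(s)

    def q_analytic(self, t_since_onset) -> np.ndarray:
        t = np.asarray(t_since_onset, dtype=float)
        return t * abs(1.0 / self.spec.proximal_period - 1.0 / self.spec.distal_period)

    def arc_length(self, t) -> np.ndarray:
        """Arc length of the oscillatory domain at recording time t."""
        return self.arc_length_initial + self.spec.growth_rate * np.asarray(t, dtype=float)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "arc_length_initial": self.arc_length_initial,
            "onset_time": self.onset_time,
            "onset_frame": int(round(self.onset_time / self.spec.frame_interval_dt)),
            "track_speeds": {str(k): v for k, v in self.track_speeds.items()},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _intensity_model(spec: PhantomSpec, gt: GroundTruth) -> Callable:
    """I(s, t) for shell material at arc distance s and recording time t."""

    def model(s, t):
        s = np.asarray(s, dtype=float)
        t = np.asarray(t, dtype=float)
        pulse = spec.pulse_amplitude * np.exp(-0.5 * ((t - spec.pulse_peak_time) / spec.pulse_width) ** 2)
        t_rel = t - gt.onset_time
        osc = np.where(
            t_rel >= 0,
            spec.oscillation_amplitude * 0.5 * (1.0 + np.cos(gt.phase(s, np.maximum(t_rel, 0.0)))),
            0.0,
        )
        return spec.background_level + pulse + osc

    return model


# ---------------------------------------------------------------------------
# egg-cylinder geometry


class _EggCylinder:
    """Hemisphere-capped cylinder shell, distal pole at low Z.

    The cylinder axis runs along Z through the lateral volume centre.  The
    rim (proximal end, wave origin) sits at ``z_rim(t)`` and moves up as
    the tissue grows; the cap is static.  Arc distance s is measured along
    the meridian from the current rim toward the distal pole.
    """

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        sp = spec.voxel_spacing
        nz, ny, nx = spec.volume_shape
        self.center_yx = np.array([(ny - 1) / 2.0 * sp, (nx - 1) / 2.0 * sp])
        self.z_pole_margin = 3.0 * sp + spec.shell_thickness / 2.0
        self.z_cap = self.z_pole_margin + spec.shell_radius  # equator plane
        self.alpha_distal = np.deg2rad(spec.distal_cap_angle_deg)

    def height(self, t) -> np.ndarray:
        return self.spec.cylinder_height + self.spec.growth_rate * np.asarray(t, dtype=float)

    def z_rim(self, t) -> np.ndarray:
        return self.z_cap + self.height(t)

    def arc_total(self, t) -> np.ndarray:
        """Arc length rim → distal end (at the configured cap angle)."""
        return self.height(t) + self.spec.shell_radius * self.alpha_distal

    def check_fits(self) -> None:
        sp = self.spec.voxel_spacing
        nz, ny, nx = self.spec.volume_shape
        t_end = self.spec.times[-1]
        z_top = float(self.z_rim(t_end)) + self.spec.shell_thickness / 2.0 + 2.0 * sp
        lateral = 2.0 * (self.spec.shell_radius + self.spec.shell_thickness / 2.0) + 4.0 * sp
        if z_top > (nz - 1) * sp or lateral > (ny - 1) * sp or lateral > (nx - 1) * sp:
            raise ValueError(
                f"volume of {self.spec.volume_shape} voxels at {sp} μm cannot contain the shell: "
                f"needs ≥ {z_top / sp:.0f} planes in Z and ≥ {lateral / sp:.0f} in Y/X "
                "(grow the volume or shrink radius/height/growth)"
            )

    def surface_point(self, s, theta, t) -> np.ndarray:
        """Mid-surface point(s) at arc distance s from the rim at time t.

        ``theta`` is the azimuth about the cylinder axis measured from +Y.
        Returns (z, y, x) μm with shape (..., 3).
        """
        s = np.asarray(s, dtype=float)
        theta = np.broadcast_to(np.asarray(theta, dtype=float), s.shape)
        R = self.spec.shell_radius
        h = self.height(t)
        on_cyl = s <= h
        z = np.where(on_cyl, self.z_rim(t) - s, np.nan)
        rho = np.where(on_cyl, R, np.nan)
        alpha = np.clip((s - h) / R, 0.0, np.pi / 2)
        z = np.where(on_cyl, z, self.z_cap - R * np.sin(alpha))
        rho = np.where(on_cyl, rho, R * np.cos(alpha))
        y = self.center_yx[0] + rho * np.cos(theta)
        x = self.center_yx[1] + rho * np.sin(theta)
        return np.stack([z, y, x], axis=-1)

    def landmark_points(self, t) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        dth = np.deg2rad(self.spec.distal_azimuth_deg)
        arc = float(self.arc_total(t))
        origin = self.surface_point(np.array(0.0), 0.0, t)
        left = self.surface_point(np.array(arc), +dth, t)
        right = self.surface_point(np.array(arc), -dth, t)
        return origin, left, right

    def landmark_set(self, keyframe_times: np.ndarray) -> LandmarkSet:
        origin = np.stack([self.landmark_points(t)[0] for t in keyframe_times])
        left = np.stack([self.landmark_points(t)[1] for t in keyframe_times])
        right = np.stack([self.landmark_points(t)[2] for t in keyframe_times])
        return LandmarkSet(
            times=keyframe_times, origin=origin, left_distal=left, right_distal=right,
            rotation_angles=(0.0, 0.0, 0.0),
        )


def generate_phantom_volume(
    spec: PhantomSpec,
    keyframe_stride: int = 10,
) -> tuple[VolumeSeries, LandmarkSet, GroundTruth]:
    """Render the 3D+t phantom volume with landmarks and ground truth.

    Shell voxels carry the intensity model evaluated at their meridional
    arc distance; everything else carries ``exterior_level``.  Gaussian
    noise (clipped at zero) is added everywhere.  Landmark keyframes are
    emitted every ``keyframe_stride`` frames (plus the final frame).
    """
    spec.validate()
    geom = _EggCylinder(spec)
    geom.check_fits()
    sp = spec.voxel_spacing
    nz, ny, nx = spec.volume_shape
    times = spec.times
    gt = GroundTruth(spec=spec, arc_length_initial=float(geom.arc_total(0.0)), onset_time=spec.onset_time)
    model = _intensity_model(spec, gt)

    z = np.arange(nz)[:, None, None] * sp
    y = np.arange(ny)[None, :, None] * sp - geom.center_yx[0]
    x = np.arange(nx)[None, None, :] * sp - geom.center_yx[1]
    rho = np.sqrt(y**2 + x**2)  # (1, ny, nx)
    R, th = spec.shell_radius, spec.shell_thickness
    # static cap shell
    r_sph = np.sqrt(rho**2 + (z - geom.z_cap) ** 2)
    cap = (z < geom.z_cap) & (np.abs(r_sph - R) <= th / 2.0)
    alpha = np.arcsin(np.clip((geom.z_cap - z) / np.maximum(r_sph, 1e-9), -1.0, 1.0))
    cyl_radial = np.abs(rho - R) <= th / 2.0  # (1, ny, nx) broadcastable

    rng = np.random.default_rng([spec.rng_seed, _STREAM_VOLUME])
    data = np.empty((spec.n_frames,) + spec.volume_shape, dtype=np.float32)
    for i, t in enumerate(times):
        h = float(geom.height(t))
        z_rim = float(geom.z_rim(t))
        frame = np.full(spec.volume_shape, spec.exterior_level, dtype=np.float32)
        cyl = cyl_radial & (z >= geom.z_cap) & (z <= z_rim)
        s_cyl = z_rim - z
        frame[np.broadcast_to(cyl, frame.shape)] = model(
            np.broadcast_to(s_cyl, frame.shape)[np.broadcast_to(cyl, frame.shape)], t
        )
        s_cap = h + R * alpha
        frame[cap] = model(np.broadcast_to(s_cap, frame.shape)[cap], t)
        if spec.noise_sd > 0:
            frame += rng.normal(0.0, spec.noise_sd, size=frame.shape).astype(np.float32)
            np.maximum(frame, 0.0, out=frame)
        data[i] = frame

    vol = VolumeSeries(data=data, voxel_spacing=(sp, sp, sp), frame_interval=spec.frame_interval_dt)
    key_idx = sorted(set(range(0, spec.n_frames, keyframe_stride)) | {spec.n_frames - 1})
    landmarks = geom.landmark_set(times[key_idx])
    gt.landmarks = landmarks
    return vol, landmarks, gt


def generate_phantom_kymograph(
    spec: PhantomSpec,
    n_rows: int | None = None,
    fill_value: float = 1067.0,
) -> tuple[Kymograph, GroundTruth]:
    """Render the 1D arc intensity model directly into a kymograph.

    Both sides carry the same profile (the phantom is bilaterally
    symmetric).  The valid extent of each column follows the growing arc
    length ``initial_arc_length + growth_rate · t``; cells beyond it hold
    ``fill_value``.
    """
    spec.validate()
    px = spec.voxel_spacing
    times = spec.times
    arc_end = spec.initial_arc_length + spec.growth_rate * times[-1]
    half_needed = int(np.floor(arc_end / px))
    if n_rows is None:
        half = half_needed
        n_rows = 2 * half + 1
    else:
        half = (n_rows - 1) // 2
        if half < half_needed:
            raise ValueError(
                f"{n_rows} rows cannot hold the final arc of {arc_end:.1f} μm "
                f"({half_needed} px per side needed)"
            )
    mid = half
    gt = GroundTruth(spec=spec, arc_length_initial=spec.initial_arc_length, onset_time=spec.onset_time)
    model = _intensity_model(spec, gt)
    s = np.abs(np.arange(n_rows) - mid) * px
    data = model(s[:, None], times[None, :])
    valid = s[:, None] <= (spec.initial_arc_length + spec.growth_rate * times)[None, :]
    rng = np.random.default_rng([spec.rng_seed, _STREAM_KYMOGRAPH])
    if spec.noise_sd > 0:
        data = np.maximum(data + rng.normal(0.0, spec.noise_sd, size=data.shape), 0.0)
    data = np.where(valid, data, float(fill_value))
    kym = Kymograph(
        data=data, valid=valid, midline_row=mid, spatial_pixel=px,
        dt=spec.frame_interval_dt, start_time=0.0, fill_value=float(fill_value),
    )
    return kym, gt


def generate_phantom_tracks(
    spec: PhantomSpec,
    seed_arc_range: tuple[float, float] = (5.0, 50.0),
    azimuth_range_deg: float = 20.0,
) -> tuple[list[CellTrack], GroundTruth]:
    """Advect cell tracks along the shell surface away from the origin.

    Each track starts at a small arc distance from the wave origin and a
    random azimuth near the LOI plane, and moves distally at a per-track
    speed drawn uniformly from ``advection_speed ± advection_speed_spread``
    (0.1–0.3 μm/min at the defaults, matching reported mesoderm motility),
    with isotropic Gaussian positional jitter.  Positions are fixed to the
    lab frame: arc distance is measured from the rim position at t = 0, so
    zero advection yields strictly stationary tracks regardless of growth.
    """
    spec.validate()
    geom = _EggCylinder(spec)
    rng = np.random.default_rng([spec.rng_seed, _STREAM_TRACKS])
    times = spec.times
    gt = GroundTruth(spec=spec, arc_length_initial=float(geom.arc_total(0.0)), onset_time=spec.onset_time)
    tracks: list[CellTrack] = []
    for tid in range(spec.n_tracks):
        s0 = rng.uniform(*seed_arc_range)
        theta = np.deg2rad(rng.uniform(-azimuth_range_deg, azimuth_range_deg))
        v = rng.uniform(
            spec.advection_speed - spec.advection_speed_spread,
            spec.advection_speed + spec.advection_speed_spread,
        )
        v = max(v, 0.0)
        s = s0 + v * times
        pos = geom.surface_point(s, theta, 0.0)
        if spec.track_jitter_sd > 0:
            pos = pos + rng.normal(0.0, spec.track_jitter_sd, size=pos.shape)
        tracks.append(CellTrack(track_id=tid, times=times.copy(), positions=pos))
        gt.track_speeds[tid] = float(v)
    gt.landmarks = geom.landmark_set(times[[0, spec.n_frames - 1]])
    return tracks, gt


def reference_paths(
    spec: PhantomSpec, t: float = 0.0, n_segments: int = 20_000
) -> tuple[SurfacePath, SurfacePath]:
    """Analytic left/right LOIs through the phantom's true anchors at time t.

    Anchors are the wave origin, the mid-arc surface point and the distal
    end on each side; used by tests and the flow stage when the full
    volume pipeline is bypassed.
    """
    geom = _EggCylinder(spec)
    arc = float(geom.arc_total(t))
    dth = np.deg2rad(spec.distal_azimuth_deg)
    paths = []
    for sign in (+1, -1):
        origin = geom.surface_point(np.array(0.0), 0.0, t)
        mid = geom.surface_point(np.array(arc / 2.0), sign * dth / 2.0, t)
        distal = geom.surface_point(np.array(arc), sign * dth, t)
        paths.append(build_surface_path(origin, mid, distal, n_segments=n_segments))
    return paths[0], paths[1]
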