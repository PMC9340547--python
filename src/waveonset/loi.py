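"""Line-of-interest geometry and kymograph sampling.

The oscillation readout lives on the curved outer surface of the mesoderm.
Its geometry is reduced to a *line of interest* (LOI) per body side: a
smooth curve through three anchors — the proximal wave origin, an
intermediate surface point, and the distal end of the presomitic mesoderm.
Intensity is collected at equal arc-length steps along the LOI and stacked
over time into a kymograph whose midline row is the wave origin, with the
left arc extending upward and the right arc downward.

Anchors are annotated in a handful of key frames and linearly interpolated
in between; the intermediate anchor is found automatically as the intensity
maximum along the ray from the embryo centre through the origin–distal
midpoint.

All physical points are ``(z, y, x)`` micrometre triplets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import UnivariateSpline

from .preprocess import VolumeSeries

__all__ = [
    "LandmarkSet",
    "FrameLandmarks",
    "SurfacePath",
    "Kymograph",
    "interpolate_landmarks",
    "locate_intermediate_point",
    "build_surface_path",
    "sample_surface_kymograph",
    "mip_kymograph",
    "transverse_section",
    "normalize_profile",
    "DEFAULT_N_SEGMENTS",
    "DEFAULT_VOLUME_SIGMA_PX",
    "DEFAULT_SPHERE_DIAMETER_PX",
    "DEFAULT_KYMO_FILL",
]

logger = logging.getLogger(__name__)

#: Number of equal-parameter chords used to tabulate arc length along the LOI.
DEFAULT_N_SEGMENTS = 100_000
#: 3D Gaussian pre-smoothing of the volume before surface sampling (pixels).
DEFAULT_VOLUME_SIGMA_PX = 6.0
#: Diameter of the spherical averaging volume per kymograph pixel (pixels).
DEFAULT_SPHERE_DIAMETER_PX = 12.0
#: Fill value marking kymograph cells beyond the arc length of a frame.
DEFAULT_KYMO_FILL = 1067.0


# ---------------------------------------------------------------------------
# landmarks


@dataclass
class LandmarkSet:
    """Keyframe anchor annotations.

    ``times`` are strictly increasing keyframe times (min); each anchor array
    has shape ``(K, 3)`` in (z, y, x) micrometres.  ``rotation_angles`` are
    optional operator-supplied axis-alignment angles in degrees.
    """

    times: np.ndarray
    origin: np.ndarray
    left_distal: np.ndarray
    right_distal: np.ndarray
    rotation_angles: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size == 0:
            raise ValueError("landmark set needs at least one keyframe")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("keyframe times must be strictly increasing")
        for name in ("origin", "left_distal", "right_distal"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.times.size, 3):
                raise ValueError(f"{name} must have shape (K, 3)")
            setattr(self, name, arr)

    def transform(self, fn) -> "LandmarkSet":
        """Return a copy with every anchor point mapped through ``fn``."""
        return LandmarkSet(
            times=self.times.copy(),
            origin=fn(self.origin),
            left_distal=fn(self.left_distal),
            right_distal=fn(self.right_distal),
            rotation_angles=self.rotation_angles,
        )


@dataclass
class FrameLandmarks:
    """Anchors interpolated to every frame time."""

    times: np.ndarray
    origin: np.ndarray
    left_distal: np.ndarray
    right_distal: np.ndarray


def interpolate_landmarks(lm: LandmarkSet, frame_times: Sequence[float]) -> FrameLandmarks:
    """Coordinate-wise linear interpolation of keyframe anchors.

    Outside the keyframe span the nearest keyframe value is held constant
    (``numpy.interp`` clamping).
    """
    t = np.asarray(frame_times, dtype=float)
    out = {}
    for name in ("origin", "left_distal", "right_distal"):
        arr = getattr(lm, name)
        out[name] = np.stack([np.interp(t, lm.times, arr[:, k]) for k in range(3)], axis=1)
    return FrameLandmarks(times=t, **out)


# ---------------------------------------------------------------------------
# surface path


class SurfacePath:
    """Smooth curve through three anchors with a chorded arc-length table.

    Three non-collinear points determine a unique circle; the path follows
    its arc from origin to distal through the intermediate anchor, which is
    exact wherever the tissue surface is locally circular (the distal dome)
    and avoids the systematic arc shortening a parabolic interpolant shows
    on curved anatomy.  Collinear anchors degenerate to the polyline
    origin → intermediate → distal.

    The curve parameter ``u`` runs over [0, 1]; arc length is tabulated by
    ``n_segments`` equal-``u`` chords, and integer-micrometre positions are
    served from that table (nearest cumulative length).
    """

    def __init__(self, origin, intermediate, distal, n_segments: int = DEFAULT_N_SEGMENTS):
        anchors = np.array([origin, intermediate, distal], dtype=float)
        if anchors.shape != (3, 3):
            raise ValueError("anchors must be three 3D points")
        d01 = np.linalg.norm(anchors[1] - anchors[0])
        d12 = np.linalg.norm(anchors[2] - anchors[1])
        d02 = np.linalg.norm(anchors[2] - anchors[0])
        if min(d01, d12, d02) < 1e-9:
            raise ValueError("coincident anchors do not define a path")
        if n_segments < 2:
            raise ValueError("need at least two chord segments")
        self.anchors = anchors
        self.n_segments = int(n_segments)

        a, b = anchors[1] - anchors[0], anchors[2] - anchors[0]
        normal = np.cross(a, b)
        area2 = np.linalg.norm(normal)
        if area2 < 1e-9 * d01 * d02:
            self._kind = "polyline"
            self._normal = _any_perpendicular(b / d02)
        else:
            self._kind = "arc"
            self._normal = normal / area2
            e1 = a / d01
            e2 = np.cross(self._normal, e1)
            # 2D circumcentre in the (e1, e2) plane through the origin anchor
            p1 = np.array([d01, 0.0])
            p2 = np.array([b @ e1, b @ e2])
            d = 2.0 * (p1[0] * p2[1] - p1[1] * p2[0])
            ux = (p1 @ p1) * p2[1] - (p2 @ p2) * p1[1]
            uy = (p2 @ p2) * p1[0] - (p1 @ p1) * p2[0]
            c2 = np.array([ux, uy]) / d
            self._center = anchors[0] + c2[0] * e1 + c2[1] * e2
            self._radius = float(np.linalg.norm(anchors[0] - self._center))
            r1 = (anchors[0] - self._center)
            self._f1 = r1 / np.linalg.norm(r1)
            self._f2 = np.cross(self._normal, self._f1)
            th_mid = self._angle_of(anchors[1])
            th_end = self._angle_of(anchors[2])
            # sweep from the origin anchor (angle 0) through the intermediate
            # to the distal anchor, in whichever rotation sense visits them
            # in that order
            ccw_mid, ccw_end = th_mid % (2 * np.pi), th_end % (2 * np.pi)
            cw_mid, cw_end = (-th_mid) % (2 * np.pi), (-th_end) % (2 * np.pi)
            if ccw_mid <= ccw_end:
                self._theta_end = ccw_end
            else:
                self._theta_end = -cw_end

        u = np.linspace(0.0, 1.0, self.n_segments + 1)
        pts = self.point_at_u(u)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self.u_table = u
        self.points = pts
        self.cumulative_length = np.concatenate([[0.0], np.cumsum(seg)])
        self.total_length = float(self.cumulative_length[-1])

    def _angle_of(self, p: np.ndarray) -> float:
        rel = p - self._center
        return float(np.arctan2(rel @ self._f2, rel @ self._f1))

    @property
    def plane_normal(self) -> np.ndarray:
        """Unit normal of the anchor plane (lateral reference direction)."""
        return self._normal

    def point_at_u(self, u) -> np.ndarray:
        """Evaluate the curve at parameter values ``u`` in [0, 1]."""
        u = np.atleast_1d(np.asarray(u, dtype=float))
        if self._kind == "polyline":
            a, m, b = self.anchors
            l1 = np.linalg.norm(m - a)
            l2 = np.linalg.norm(b - m)
            split = l1 / (l1 + l2)
            pts = np.where(
                (u <= split)[:, None],
                a + np.outer(u / max(split, 1e-300), m - a),
                m + np.outer((u - split) / max(1.0 - split, 1e-300), b - m),
            )
            return pts
        th = u * self._theta_end
        return (
            self._center
            + self._radius * np.outer(np.cos(th), self._f1)
            + self._radius * np.outer(np.sin(th), self._f2)
        )

    def u_at_arc(self, distances) -> np.ndarray:
        """Parameter values whose cumulative length is nearest each distance."""
        d = np.atleast_1d(np.asarray(distances, dtype=float))
        idx = np.searchsorted(self.cumulative_length, d)
        idx = np.clip(idx, 1, self.n_segments)
        below = self.cumulative_length[idx - 1]
        above = self.cumulative_length[idx]
        pick = np.where(np.abs(d - below) <= np.abs(above - d), idx - 1, idx)
        return self.u_table[pick]

    def point_at_arc(self, distances) -> np.ndarray:
        """Curve points at given arc distances (via the chord table)."""
        return self.point_at_u(self.u_at_arc(distances))

    def arc_points(self, step: float = 1.0) -> np.ndarray:
        """Points at every integer multiple of ``step`` below the total length."""
        d = np.arange(0.0, np.floor(self.total_length / step) * step + step / 2, step)
        return self.point_at_arc(d)


def _any_perpendicular(v: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, trial)
    return p / np.linalg.norm(p)


def build_surface_path(origin, intermediate, distal, n_segments: int = DEFAULT_N_SEGMENTS) -> SurfacePath:
    """Fit the LOI through the three anchors and tabulate its arc length."""
    return SurfacePath(origin, intermediate, distal, n_segments=n_segments)


# ---------------------------------------------------------------------------
# intermediate anchor search


def locate_intermediate_point(
    vol: VolumeSeries,
    com: Sequence[float],
    origin: np.ndarray,
    distal: np.ndarray,
    step_um: float | None = None,
    time_smoothing: float | None = None,
) -> np.ndarray:
    """Find the mid-arc surface anchor per frame by radial intensity maximum.

    For each frame the ray from the embryo centre ``com`` through the
    midpoint of origin and distal is sampled out to the volume border; the
    position of the intensity maximum (first maximum on ties, i.e. closest
    to the centre) marks the tissue surface.  A cubic smoothing spline over
    time replaces the raw per-frame maxima, suppressing voxel-level jitter.

    ``origin`` and ``distal`` are ``(T, 3)`` per-frame anchor arrays;
    returns a ``(T, 3)`` array of smoothed intermediate anchors in μm.
    """
    com = np.asarray(com, dtype=float)
    spacing = np.array(vol.voxel_spacing)
    if step_um is None:
        step_um = 0.5 * float(spacing.min())
    extent = (np.array(vol.frame_shape) - 1) * spacing
    T = vol.n_frames
    raw = np.empty((T, 3))
    for t in range(T):
        mid = (origin[t] + distal[t]) / 2.0
        direction = mid - com
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            raise ValueError(f"degenerate geometry at frame {t}: COM coincides with the arc midpoint")
        direction = direction / norm
        # longest in-bounds travel along the ray
        with np.errstate(divide="ignore"):
            bounds = np.where(direction > 0, (extent - com) / direction,
                              np.where(direction < 0, -com / direction, np.inf))
        r_max = float(np.min(bounds))
        r = np.arange(0.0, max(r_max, step_um), step_um)
        pts_vox = (com[None, :] + r[:, None] * direction[None, :]) / spacing
        profile = ndimage.map_coordinates(vol.data[t].astype(np.float32), pts_vox.T, order=1, mode="nearest")
        raw[t] = com + r[int(np.argmax(profile))] * direction
    if T < 4:
        return raw
    times = vol.times
    if time_smoothing is None:
        time_smoothing = T * float(spacing.min()) ** 2
    out = np.empty_like(raw)
    for k in range(3):
        spl = UnivariateSpline(times, raw[:, k], k=3, s=time_smoothing)
        out[:, k] = spl(times)
    return out


# ---------------------------------------------------------------------------
# kymographs


@dataclass
class Kymograph:
    """Midline-centred space × time intensity matrix.

    Row ``midline_row`` is the wave origin; rows above it follow the left
    arc outward, rows below the right arc.  Cells beyond the arc length of
    a frame are invalid and carry ``fill_value``.
    """

    data: np.ndarray
    valid: np.ndarray
    midline_row: int
    spatial_pixel: float
    dt: float
    start_time: float = 0.0
    fill_value: float = DEFAULT_KYMO_FILL

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.data.shape != self.valid.shape or self.data.ndim != 2:
            raise ValueError("kymograph data and validity mask must be matching 2D arrays")
        if not 0 <= self.midline_row < self.data.shape[0]:
            raise ValueError("midline row outside the matrix")
        if self.spatial_pixel <= 0 or self.dt <= 0:
            raise ValueError("spatial pixel and dt must be positive")
        fill = self.fill_value
        bad = ~self.valid
        if np.isnan(fill):
            ok = np.all(np.isnan(self.data[bad]))
        else:
            ok = np.allclose(self.data[bad], fill, equal_nan=True)
        if not ok:
            raise ValueError("invalid cells must carry the fill value")

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.dt * np.arange(self.n_frames)

    def half(self, side: str = "left") -> tuple[np.ndarray, np.ndarray]:
        """One side of the matrix ordered midline → distal (row 0 = midline)."""
        if side == "left":
            sl = slice(self.midline_row, None, -1)
        elif side == "right":
            sl = slice(self.midline_row, None)
        else:
            raise ValueError("side must be 'left' or 'right'")
        return self.data[sl], self.valid[sl]


def _sphere_offsets(diameter_px: float) -> np.ndarray:
    r = diameter_px / 2.0
    n = int(np.floor(r))
    g = np.arange(-n, n + 1)
    zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
    keep = zz**2 + yy**2 + xx**2 <= r**2
    return np.stack([zz[keep], yy[keep], xx[keep]], axis=1)


def _sphere_means(frame: np.ndarray, centers_vox: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Mean intensity in a voxel sphere around each centre (partial at borders)."""
    idx = np.round(centers_vox).astype(int)[:, None, :] + offsets[None, :, :]
    shape = np.array(frame.shape)
    inb = np.all((idx >= 0) & (idx < shape), axis=2)
    n_out = int((~inb).any(axis=1).sum())
    if n_out:
        logger.debug("%d sampling spheres extend outside the volume; partial means used", n_out)
    idx_c = np.clip(idx, 0, shape - 1)
    vals = frame[idx_c[..., 0], idx_c[..., 1], idx_c[..., 2]]
    vals = np.where(inb, vals, 0.0)
    counts = inb.sum(axis=1)
    counts = np.maximum(counts, 1)
    return vals.sum(axis=1) / counts


def sample_surface_kymograph(
    vol: VolumeSeries,
    left_paths: Sequence[SurfacePath],
    right_paths: Sequence[SurfacePath],
    smoothing_sigma_px: float = DEFAULT_VOLUME_SIGMA_PX,
    sphere_diameter_px: float = DEFAULT_SPHERE_DIAMETER_PX,
    fill_value: float = DEFAULT_KYMO_FILL,
) -> Kymograph:
    """Collect the surface kymograph along per-frame left/right LOIs.

    The volume is pre-smoothed with a 3D Gaussian; at every integer arc
    distance the mean intensity in a sphere centred on the LOI is one
    kymograph pixel.  The origin's series sits on the midline; the left arc
    extends upward, the right arc downward.  One spatial pixel equals one
    (isotropic) voxel spacing of arc distance.
    """
    if not vol.is_isotropic:
        raise ValueError("surface sampling requires an isotropic volume; resample first")
    if len(left_paths) != vol.n_frames or len(right_paths) != vol.n_frames:
        raise ValueError("need one left and one right path per frame")
    px = vol.voxel_spacing[0]
    offsets = _sphere_offsets(sphere_diameter_px)
    n_left = [int(np.floor(p.total_length / px)) for p in left_paths]
    n_right = [int(np.floor(p.total_length / px)) for p in right_paths]
    mid = max(n_left)
    rows = mid + max(n_right) + 1
    data = np.full((rows, vol.n_frames), float(fill_value))
    valid = np.zeros((rows, vol.n_frames), dtype=bool)
    spacing = np.array(vol.voxel_spacing)
    for t in range(vol.n_frames):
        frame = ndimage.gaussian_filter(vol.data[t].astype(np.float32), smoothing_sigma_px)
        for side, paths, n_side, sign in (("left", left_paths, n_left, -1), ("right", right_paths, n_right, +1)):
            d = np.arange(0.0, (n_side[t] + 0.5) * px, px)
            pts = paths[t].point_at_arc(d) / spacing
            vals = _sphere_means(frame, pts, offsets)
            r_idx = mid + sign * np.arange(vals.size)
            data[r_idx, t] = vals
            valid[r_idx, t] = True
    return Kymograph(
        data=data, valid=valid, midline_row=mid, spatial_pixel=px,
        dt=vol.frame_interval, start_time=vol.start_time, fill_value=float(fill_value),
    )


def mip_kymograph(
    vol: VolumeSeries,
    paths: Sequence[SurfacePath],
    projection_axis: str = "z",
    corridor_um: float = 25.0,
    gaussian_sigma_um: float = 12.0,
    fill_value: float = DEFAULT_KYMO_FILL,
) -> Kymograph:
    """Projection kymograph: corridor-averaged intensity along a 2D spline.

    Each frame is reduced to a maximum intensity projection along Y or Z,
    smoothed with a 2D Gaussian, and averaged across a corridor of the given
    width perpendicular to the per-frame path.  ``paths`` must live in the
    projection plane (the projected coordinate is ignored).
    """
    axis_idx = {"z": 1, "y": 2}.get(projection_axis)
    if axis_idx is None:
        raise ValueError("projection axis must be 'z' or 'y'")
    plane_axes = [a for a in (0, 1, 2) if a != axis_idx - 1]  # axes of the MIP plane, in (z,y,x) order
    spacing = np.array(vol.voxel_spacing)[plane_axes]
    img_shape = np.array(vol.frame_shape)[plane_axes]
    if corridor_um > min(img_shape * spacing):
        raise ValueError(f"corridor of {corridor_um} μm is wider than the projected image")
    if len(paths) != vol.n_frames:
        raise ValueError("need one path per frame")
    px = float(spacing.min())
    n_rows = max(int(np.floor(p.total_length / px)) + 1 for p in paths)
    data = np.full((n_rows, vol.n_frames), float(fill_value))
    valid = np.zeros((n_rows, vol.n_frames), dtype=bool)
    half = corridor_um / 2.0
    offs = np.arange(-np.floor(half / px), np.floor(half / px) + 0.5) * px
    for t in range(vol.n_frames):
        mip = vol.data[t].astype(np.float32).max(axis=axis_idx - 1)
        mip = ndimage.gaussian_filter(mip, gaussian_sigma_um / spacing)
        path = paths[t]
        d = np.arange(0.0, path.total_length, px)
        pts = path.point_at_arc(d)[:, plane_axes]
        nxt = path.point_at_arc(np.minimum(d + px, path.total_length))[:, plane_axes]
        tang = nxt - pts
        tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
        norm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
        samp = pts[:, None, :] + offs[None, :, None] * norm[:, None, :]
        coords = (samp / spacing).reshape(-1, 2).T
        vals = ndimage.map_coordinates(mip, coords, order=1, mode="nearest").reshape(len(d), offs.size)
        data[: len(d), t] = vals.mean(axis=1)
        valid[: len(d), t] = True
    return Kymograph(
        data=data, valid=valid, midline_row=0, spatial_pixel=px,
        dt=vol.frame_interval, start_time=vol.start_time, fill_value=float(fill_value),
    )


def transverse_section(
    vol: VolumeSeries,
    frame: int,
    domain_extent_um: tuple[float, float] | None,
    fraction: float = 0.5,
    slab_um: float = 12.0,
) -> np.ndarray:
    """XY maximum intensity projection of a thin slab across the body axis.

    The slab is centred at ``fraction`` of the annotated expression-domain
    extent along Z (proximodistal axis) and spans ``slab_um`` micrometres.
    """
    if domain_extent_um is None:
        raise ValueError("expression-domain annotation required to place the section")
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    z0, z1 = sorted(float(v) for v in domain_extent_um)
    zc = z0 + fraction * (z1 - z0)
    dz = vol.voxel_spacing[0]
    lo = int(np.floor((zc - slab_um / 2.0) / dz + 0.5))
    hi = int(np.floor((zc + slab_um / 2.0) / dz + 0.5))
    hi = max(hi, lo + 1)
    nz = vol.frame_shape[0]
    if lo < 0 or hi > nz:
        raise ValueError("slab does not fit inside the volume")
    return vol.data[frame, lo:hi].max(axis=0)


# ---------------------------------------------------------------------------
# profiles


def normalize_profile(
    profile: np.ndarray,
    lowess_frac: float = 0.06,
    smooth: bool = True,
    subtract_background: bool = True,
    normalize_max: bool = True,
) -> np.ndarray:
    """LOWESS-smooth a spatial intensity profile and rescale it to [0, 1].

    Smoothing uses locally weighted linear regression with fractional
    bandwidth ``lowess_frac``; the profile minimum is then treated as
    background and the result divided by its maximum.  With all switches
    off the profile passes through untouched (raw plotting mode).
    """
    y = np.asarray(profile, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("profile must be 1D with at least 3 samples")
    out = y.copy()
    if smooth:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        frac = max(lowess_frac, 3.0 / y.size)
        x = np.arange(y.size, dtype=float)
        out = lowess(out, x, frac=frac, return_sorted=False)
    if subtract_background:
        out = out - out.min()
    if normalize_max:
        peak = out.max()
        if peak <= 0:
            warnings.warn("profile has no dynamic range; returning zeros", RuntimeWarning, stacklevel=2)
            return np.zeros_like(out)
        out = out / peak
    return out
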