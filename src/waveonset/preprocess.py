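"""Volume conditioning ahead of geometry extraction.

The raw input is a 3D+t single-channel intensity series. Before any surface
geometry can be extracted the series is (i) background-reduced with a fixed
reference box outside the specimen, (ii) registered recursively frame to
frame, (iii) translated/rotated so the embryo's centre of mass sits at the
image centre with the proximodistal axis along Z, and (iv) resampled to an
isotropic voxel grid.  All operations return new :class:`VolumeSeries`
objects; nothing is modified in place unless documented.

Axis convention: arrays are indexed ``(T, Z, Y, X)``; physical points are
``(z, y, x)`` in micrometres with the origin at the centre of the first
voxel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeSeries",
    "AlignmentResult",
    "subtract_temporal_background",
    "register_recursive",
    "align_by_mask_com",
    "resample_isotropic",
    "subsample_xy",
    "translation_estimator_xcorr",
    "DEFAULT_BACKGROUND_BOX_SHAPE",
    "DEFAULT_BACKGROUND_OFFSET",
    "DEFAULT_MASK_THRESHOLD",
    "DEFAULT_Z_FACTOR",
]

#: Reference box averaged per frame for temporal background estimation,
#: as a (Z, Y, X) voxel shape anchored at the volume corner by default.
DEFAULT_BACKGROUND_BOX_SHAPE = (150, 30, 30)
#: Counts added back after background subtraction so intensities stay positive.
DEFAULT_BACKGROUND_OFFSET = 1000.0
#: Binary-mask threshold used for the summed-mask centre-of-mass alignment.
DEFAULT_MASK_THRESHOLD = 1030.0
#: Z resampling factor turning the native anisotropic grid isotropic.
DEFAULT_Z_FACTOR = 3.59


@dataclass
class VolumeSeries:
    """A 3D+t intensity series with physical calibration.

    Parameters
    ----------
    data
        Array of shape ``(T, Z, Y, X)``, non-negative counts.
    voxel_spacing
        ``(z, y, x)`` spacing in micrometres.
    frame_interval
        Time between consecutive frames in minutes.
    start_time
        Acquisition time of the first frame in minutes.
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float]
    frame_interval: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"expected (T, Z, Y, X) data, got shape {self.data.shape}")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be three positive values, got {self.voxel_spacing}")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        if self.data.size and float(self.data.min()) < 0:
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in minutes."""
        return self.start_time + self.frame_interval * np.arange(self.n_frames)

    @property
    def is_isotropic(self) -> bool:
        sp = self.voxel_spacing
        return abs(sp[0] - sp[1]) < 1e-9 and abs(sp[1] - sp[2]) < 1e-9

    def replace(self, **changes) -> "VolumeSeries":
        return dataclasses.replace(self, **changes)

    def center_um(self) -> np.ndarray:
        """Physical (z, y, x) coordinate of the image centre."""
        shape = np.array(self.frame_shape, dtype=float)
        return (shape - 1.0) / 2.0 * np.array(self.voxel_spacing)


@dataclass
class AlignmentResult:
    """Outcome of summed-mask centre-of-mass alignment.

    ``translation_vox`` is the integer voxel shift applied to every frame;
    ``rotation_deg`` are the (z, y, x)-axis rotation angles applied about
    the image centre after translation.
    """

    translation_vox: tuple[int, int, int]
    translation_um: tuple[float, float, float]
    rotation_deg: tuple[float, float, float]
    com_vox: tuple[float, float, float]
    com_um: tuple[float, float, float]
    mask_voxels: int
    center_um: tuple[float, float, float]
    voxel_spacing: tuple[float, float, float]

    def apply_to_points(self, points_um: np.ndarray) -> np.ndarray:
        """Map physical (z, y, x) points through the same transform.

        Translation first, then the rotations about the image centre in the
        same order they are applied to the volume (z-axis, y-axis, x-axis).
        """
        pts = np.atleast_2d(np.asarray(points_um, dtype=float)) + np.array(self.translation_um)
        center = np.array(self.center_um)
        rel = pts - center
        for axis, angle in zip((0, 1, 2), self.rotation_deg):
            if angle == 0.0:
                continue
            plane = [a for a in (0, 1, 2) if a != axis]
            th = np.deg2rad(angle)
            c, s = np.cos(th), np.sin(th)
            u, v = rel[:, plane[0]].copy(), rel[:, plane[1]].copy()
            # matches scipy.ndimage.rotate on the corresponding axes pair
            rel[:, plane[0]] = c * u - s * v
            rel[:, plane[1]] = s * u + c * v
        out = rel + center
        return out if np.asarray(points_um).ndim == 2 else out[0]


def _check_box(box, shape) -> tuple[slice, slice, slice]:
    box = tuple(tuple(int(v) for v in ax) for ax in box)
    if len(box) != 3:
        raise ValueError(f"background box must give (lo, hi) per axis, got {box!r}")
    for (lo, hi), n in zip(box, shape):
        if not (0 <= lo < hi <= n):
            raise IndexError(f"background box {box!r} outside volume bounds {tuple(shape)}")
    return tuple(slice(lo, hi) for lo, hi in box)


def subtract_temporal_background(
    vol: VolumeSeries,
    bg_box: Sequence[Sequence[int]] | None = None,
    offset: float = DEFAULT_BACKGROUND_OFFSET,
) -> VolumeSeries:
    """Subtract the per-frame mean of a fixed reference box, then add ``offset``.

    The box must lie outside the specimen; its mean tracks slow background
    drift (laser power, ambient light) per frame.  After subtraction the
    constant ``offset`` is added and values are floored at zero, so the box
    region's mean is pinned at ``offset`` in the output.
    """
    if bg_box is None:
        bg_box = tuple((0, min(n, d)) for n, d in zip(DEFAULT_BACKGROUND_BOX_SHAPE, vol.frame_shape))
    sl = _check_box(bg_box, vol.frame_shape)
    out = np.empty_like(vol.data, dtype=np.float32)
    for t in range(vol.n_frames):
        frame = vol.data[t].astype(np.float32)
        bg = float(frame[sl].mean())
        np.maximum(frame - bg + offset, 0.0, out=out[t])
    return vol.replace(data=out)


def _translate_int(frame: np.ndarray, shift: Sequence[int], fill: float) -> np.ndarray:
    """Shift a 3D frame by integer voxels, filling exposed regions."""
    out = np.full_like(frame, fill)
    src = []
    dst = []
    for n, s in zip(frame.shape, shift):
        s = int(s)
        if abs(s) >= n:
            return out
        if s >= 0:
            dst.append(slice(s, n))
            src.append(slice(0, n - s))
        else:
            dst.append(slice(0, n + s))
            src.append(slice(-s, n))
    out[tuple(dst)] = frame[tuple(src)]
    return out


def translation_estimator_xcorr(fixed: np.ndarray, moving: np.ndarray) -> tuple[int, int, int]:
    """Integer-voxel translation aligning ``moving`` onto ``fixed``.

    Uses the Fourier cross-correlation peak (phase correlation with whole-pixel
    precision).  Returned shift is the vector to apply to ``moving``.
    """
    from skimage.registration import phase_cross_correlation

    shift, _, _ = phase_cross_correlation(fixed, moving, upsample_factor=1, normalization=None)
    return tuple(int(round(s)) for s in shift)


def register_recursive(
    vol: VolumeSeries,
    pairwise_estimator: Callable[[np.ndarray, np.ndarray], Sequence[int]] | None = None,
    reference_index: int = 0,
    fill_value: float = DEFAULT_BACKGROUND_OFFSET,
) -> tuple[VolumeSeries, list[tuple[int, int, int]]]:
    """Register a time series by recursive reference propagation.

    The reference frame is left untouched.  Each neighbouring frame is
    aligned against the *already registered* previous frame and the result
    becomes the reference for the next one; if ``reference_index`` is not at
    either end, propagation runs in both directions.  The default pairwise
    estimator is a translation-only cross-correlation peak; any callable
    ``(fixed, moving) -> (dz, dy, dx)`` may be substituted.

    Returns the registered series and the per-frame shifts (voxels).
    """
    T = vol.n_frames
    if not 0 <= reference_index < T:
        raise ValueError(f"reference index {reference_index} outside 0..{T - 1}")
    est = pairwise_estimator or translation_estimator_xcorr
    out = np.empty_like(vol.data, dtype=np.float32)
    out[reference_index] = vol.data[reference_index]
    shifts: list[tuple[int, int, int]] = [(0, 0, 0)] * T
    for direction in (+1, -1):
        n = reference_index
        while 0 <= n + direction < T:
            m = n + direction
            try:
                shift = tuple(int(s) for s in est(out[n], vol.data[m].astype(np.float32)))
            except Exception as exc:  # pragma: no cover - estimator contract
                raise RuntimeError(f"pairwise registration failed between frames {n} and {m}") from exc
            out[m] = _translate_int(vol.data[m].astype(np.float32), shift, fill_value)
            shifts[m] = shift
            n = m
    return vol.replace(data=out), shifts


def align_by_mask_com(
    vol: VolumeSeries,
    threshold: float = DEFAULT_MASK_THRESHOLD,
    rotation_angles: Sequence[float] = (0.0, 0.0, 0.0),
    fill_value: float = DEFAULT_BACKGROUND_OFFSET,
) -> tuple[VolumeSeries, AlignmentResult]:
    """Centre the specimen via the COM of the time-summed threshold mask.

    Per-frame binary masks (``intensity > threshold``) are summed over all
    frames; the centre of mass of the sum defines the embryo centre.  The
    whole 4D set is translated (whole voxels) so that centre lands on the
    image centre, then rotated by the operator-supplied angles about it so
    the anatomical axes line up with the image axes.
    """
    summed = np.zeros(vol.frame_shape, dtype=np.float64)
    for t in range(vol.n_frames):
        summed += vol.data[t] > threshold
    total = summed.sum()
    if total == 0:
        raise ValueError(f"no voxel above mask threshold {threshold}; cannot align")
    com_vox = np.array(ndimage.center_of_mass(summed))
    center_vox = (np.array(vol.frame_shape, dtype=float) - 1.0) / 2.0
    shift_vox = np.round(center_vox - com_vox).astype(int)
    spacing = np.array(vol.voxel_spacing)
    out = np.empty_like(vol.data, dtype=np.float32)
    for t in range(vol.n_frames):
        out[t] = _translate_int(vol.data[t].astype(np.float32), shift_vox, fill_value)
    rotation_angles = tuple(float(a) for a in rotation_angles)
    for axis, angle in zip((0, 1, 2), rotation_angles):
        if angle == 0.0:
            continue
        plane = [a for a in (0, 1, 2) if a != axis]
        for t in range(vol.n_frames):
            out[t] = ndimage.rotate(
                out[t], angle, axes=(plane[0], plane[1]), reshape=False,
                order=1, mode="constant", cval=fill_value,
            )
    result = AlignmentResult(
        translation_vox=tuple(int(s) for s in shift_vox),
        translation_um=tuple(float(s) for s in shift_vox * spacing),
        rotation_deg=rotation_angles,
        com_vox=tuple(float(c) for c in com_vox),
        com_um=tuple(float(c) for c in com_vox * spacing),
        mask_voxels=int((summed > 0).sum()),
        center_um=tuple(float(c) for c in center_vox * spacing),
        voxel_spacing=vol.voxel_spacing,
    )
    return vol.replace(data=out), result


def resample_isotropic(vol: VolumeSeries, z_factor: float = DEFAULT_Z_FACTOR) -> VolumeSeries:
    """Linearly resample along Z so the voxel grid becomes isotropic.

    X and Y are untouched; the Z spacing is divided by ``z_factor``.
    """
    if z_factor <= 0:
        raise ValueError("z factor must be positive")
    if z_factor == 1.0:
        return vol.replace(data=vol.data.copy())
    nz = vol.frame_shape[0]
    new_nz = int(round(nz * z_factor))
    old_pos = np.arange(nz, dtype=float)
    new_pos = np.linspace(0.0, nz - 1.0, new_nz)
    out = np.empty((vol.n_frames, new_nz) + vol.frame_shape[1:], dtype=np.float32)
    for t in range(vol.n_frames):
        frame = vol.data[t].astype(np.float32)
        idx = np.clip(np.searchsorted(old_pos, new_pos, side="right") - 1, 0, nz - 2)
        w = (new_pos - old_pos[idx])[:, None, None]
        out[t] = frame[idx] * (1.0 - w) + frame[idx + 1] * w
    sp = vol.voxel_spacing
    return vol.replace(data=out, voxel_spacing=(sp[0] / z_factor, sp[1], sp[2]))


def subsample_xy(vol: VolumeSeries, factor: float) -> VolumeSeries:
    """Downsample X and Y by ``factor`` (block mean for integers, linear otherwise)."""
    if factor < 1:
        raise ValueError("subsampling factor must be >= 1")
    if factor == 1:
        return vol.replace(data=vol.data.copy())
    _, ny, nx = vol.frame_shape
    if int(factor) == factor:
        f = int(factor)
        my, mx = ny // f, nx // f
        if my < 2 or mx < 2:
            raise ValueError(f"factor {factor} leaves fewer than 2 voxels along Y or X")
        out = (
            vol.data[:, :, : my * f, : mx * f]
            .reshape(vol.n_frames, -1, my, f, mx, f)
            .mean(axis=(3, 5), dtype=np.float32)
        )
    else:
        my, mx = int(round(ny / factor)), int(round(nx / factor))
        if my < 2 or mx < 2:
            raise ValueError(f"factor {factor} leaves fewer than 2 voxels along Y or X")
        out = np.empty((vol.n_frames, vol.frame_shape[0], my, mx), dtype=np.float32)
        for t in range(vol.n_frames):
            out[t] = ndimage.zoom(
                vol.data[t].astype(np.float32), (1.0, my / ny, mx / nx), order=1,
                mode="nearest", grid_mode=False,
            )
    sp = vol.voxel_spacing
    return vol.replace(data=out, voxel_spacing=(sp[0], sp[1] * factor, sp[2] * factor))
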