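"""Headline wave statistics: wave number, tissue length, phase-gradient
slope, and proximal/distal period sampling.

The wave number q is the total phase difference accumulated between the
wave origin (kymograph midline) and the distal end of the tissue, divided
by 2π: q = 1 means one full wave spans the domain.  Dividing q by the
tissue length along the surface gives the linear phase-gradient slope.
Period gradients are sampled from two time series of the intensity
kymograph — the midline (proximal) and a contour tracking the moving
domain boundary shifted inward (distal) — through the same wavelet chain
used for phase extraction.

Conventions follow the measurement protocol: one body side only (left /
top half by default), 20 pixels cropped or shifted at the distal end to
stay clear of the domain boundary, periods collected 2–6 h after wave
onset and summarised as median and interquartile range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .loi import Kymograph
from .spectral import (
    DEFAULT_CUTOFF_PERIOD,
    PhaseKymograph,
    default_period_grid,
    extract_ridge,
    morlet_spectrum,
    sinc_detrend,
)

__all__ = [
    "WaveStatSeries",
    "PeriodGradient",
    "compute_wave_number",
    "mesoderm_length",
    "compute_phase_gradient_slope",
    "compute_wave_stats",
    "sample_period_gradient",
    "DEFAULT_DISTAL_CROP_PX",
    "DEFAULT_DISTAL_SHIFT_PX",
    "DEFAULT_CORRIDOR_PX",
    "DEFAULT_PERIOD_WINDOW_MIN",
]

#: Pixels cropped from the distal end of each phase column before unwrapping.
DEFAULT_DISTAL_CROP_PX = 20
#: Inward shift of the boundary contour for the distal period series (px).
DEFAULT_DISTAL_SHIFT_PX = 20
#: Corridor width averaged around each period-series path (px).
DEFAULT_CORRIDOR_PX = 8
#: Window after wave onset in which period samples are collected (min).
DEFAULT_PERIOD_WINDOW_MIN = (120.0, 360.0)


def _column_extent(valid_half: np.ndarray, distal_crop_px: int) -> np.ndarray:
    """Per-column index of the last retained cell (midline-outward), or -1.

    ``valid_half`` is ordered midline → distal (row 0 = midline).  Only the
    contiguous valid run starting at the midline counts; the distal crop is
    removed from its far end.
    """
    n_rows, T = valid_half.shape
    ext = np.full(T, -1, dtype=int)
    for t in range(T):
        col = valid_half[:, t]
        if not col[0]:
            continue
        stop = np.flatnonzero(~col)
        run_end = int(stop[0]) if stop.size else n_rows  # exclusive
        ext[t] = run_end - 1 - distal_crop_px
    return ext


def compute_wave_number(
    pk: PhaseKymograph,
    distal_crop_px: int = DEFAULT_DISTAL_CROP_PX,
    side: str = "left",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time wave number q from one side of the phase kymograph.

    Each column's phases are unwrapped from the midline outward over the
    contiguous valid run; after cropping ``distal_crop_px`` cells at the
    distal end, q = |φ_distal − φ_midline| / 2π.  Returns ``(q, defined)``;
    columns with fewer than two usable cells are flagged undefined.
    """
    phases, valid = pk.half(side)
    ext = _column_extent(valid, distal_crop_px)
    T = phases.shape[1]
    q = np.full(T, np.nan)
    defined = ext >= 1
    for t in np.flatnonzero(defined):
        phi = np.unwrap(phases[: ext[t] + 1, t])
        q[t] = abs(phi[-1] - phi[0]) / (2.0 * np.pi)
    return q, defined


def mesoderm_length(
    pk: PhaseKymograph,
    distal_crop_px: int = DEFAULT_DISTAL_CROP_PX,
    side: str = "left",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-time tissue length along the surface, from the cropped column.

    The retained column spans ``ext`` pixels from the midline; its physical
    length ``ext × spatial_pixel`` estimates the arc length of the
    oscillatory field on that side.  Returns ``(L, defined)``.
    """
    _, valid = pk.half(side)
    ext = _column_extent(valid, distal_crop_px)
    defined = ext >= 1
    L = np.where(defined, ext * pk.spatial_pixel, np.nan)
    return L, defined


def compute_phase_gradient_slope(
    q: np.ndarray, L: np.ndarray, defined: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """slope(t) = q(t) / L(t), undefined where either input is."""
    q = np.asarray(q, dtype=float)
    L = np.asarray(L, dtype=float)
    if q.shape != L.shape:
        raise ValueError("q and L must be aligned in time")
    ok = np.isfinite(q) & np.isfinite(L) & (L > 0)
    if defined is not None:
        ok &= np.asarray(defined, dtype=bool)
    slope = np.full_like(q, np.nan)
    np.divide(q, L, out=slope, where=ok)
    return slope, ok


def _summary(values: np.ndarray) -> dict[str, float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return {"median": float("nan"), "iqr": float("nan"), "n": 0}
    q25, q50, q75 = np.percentile(v, [25.0, 50.0, 75.0])
    return {"median": float(q50), "iqr": float(q75 - q25), "n": int(v.size)}


@dataclass
class WaveStatSeries:
    """Wave number, tissue length and phase-gradient slope over time.

    ``slope * L`` reconstructs ``q`` exactly wherever defined.  Summaries
    are median/IQR over the defined time points.
    """

    times: np.ndarray
    q: np.ndarray
    L: np.ndarray
    slope: np.ndarray
    defined: np.ndarray
    side: str
    distal_crop_px: int
    summary: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summary:
            self.summary = {
                "wave_number": _summary(self.q[self.defined]),
                "mesoderm_length": _summary(self.L[self.defined]),
                "slope": _summary(self.slope[self.defined]),
            }


def compute_wave_stats(
    pk: PhaseKymograph,
    distal_crop_px: int = DEFAULT_DISTAL_CROP_PX,
    side: str = "left",
) -> WaveStatSeries:
    """Bundle q(t), L(t) and slope(t) from one side of a phase kymograph."""
    q, q_def = compute_wave_number(pk, distal_crop_px, side)
    L, L_def = mesoderm_length(pk, distal_crop_px, side)
    slope, ok = compute_phase_gradient_slope(q, L, q_def & L_def)
    return WaveStatSeries(
        times=pk.times, q=q, L=L, slope=slope, defined=ok,
        side=side, distal_crop_px=distal_crop_px,
    )


@dataclass
class PeriodGradient:
    """Proximal vs distal instantaneous periods and their window samples."""

    times: np.ndarray
    proximal_period: np.ndarray
    distal_period: np.ndarray
    in_window: np.ndarray
    proximal_samples: np.ndarray
    distal_samples: np.ndarray
    proximal: dict[str, float]
    distal: dict[str, float]
    window_min: tuple[float, float]
    side: str

    @property
    def median_difference(self) -> float:
        return self.distal["median"] - self.proximal["median"]


def _corridor_series(
    data: np.ndarray, valid: np.ndarray, centers: np.ndarray, corridor_px: int
) -> np.ndarray:
    """Mean over a row corridor centred per column on ``centers``."""
    T = data.shape[1]
    lo = centers - corridor_px // 2
    hi = lo + corridor_px
    out = np.full(T, np.nan)
    for t in range(T):
        a, b = max(lo[t], 0), min(hi[t], data.shape[0])
        if a >= b:
            continue
        col = data[a:b, t]
        ok = valid[a:b, t]
        if ok.any():
            out[t] = col[ok].mean()
    return out


def sample_period_gradient(
    kymo: Kymograph,
    onset_frame: int,
    window_min: tuple[float, float] = DEFAULT_PERIOD_WINDOW_MIN,
    distal_shift_px: int = DEFAULT_DISTAL_SHIFT_PX,
    corridor_px: int = DEFAULT_CORRIDOR_PX,
    side: str = "left",
    cutoff_period: float = DEFAULT_CUTOFF_PERIOD,
    periods: np.ndarray | None = None,
) -> PeriodGradient:
    """Measure the proximal-vs-distal period gradient from an intensity kymograph.

    The proximal series is the corridor mean around the midline; the distal
    series follows the kymograph boundary contour of the chosen side,
    shifted toward the midline by ``distal_shift_px`` so it stays inside
    the oscillatory domain while moving with the expanding tissue.  Both
    series are detrended, wavelet transformed and ridge-traced; period
    values with time-after-onset in ``(window_min[0], window_min[1]]`` are
    the samples summarised as median and IQR.
    """
    if periods is None:
        periods = default_period_grid()
    dt = kymo.dt
    data = kymo.data[:, onset_frame:]
    valid = kymo.valid[:, onset_frame:]
    T = data.shape[1]
    t_rel = dt * np.arange(T)
    if window_min[1] > t_rel[-1]:
        raise ValueError(
            f"sampling window {window_min} min exceeds the {t_rel[-1]} min recorded after onset"
        )
    mid = kymo.midline_row
    sign = -1 if side == "left" else +1
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")

    prox_centers = np.full(T, mid, dtype=int)
    proximal = _corridor_series(data, valid, prox_centers, corridor_px)

    # boundary contour of the chosen side, shifted inward
    dist_centers = np.full(T, -1, dtype=int)
    for t in range(T):
        col = valid[mid::-1, t] if sign == -1 else valid[mid:, t]
        run = np.flatnonzero(~col)
        extent = int(run[0]) - 1 if run.size else col.size - 1
        dist_centers[t] = mid + sign * max(extent - distal_shift_px, 0)
    distal = _corridor_series(data, valid, dist_centers, corridor_px)

    def ridge_periods(series: np.ndarray) -> np.ndarray:
        ok = np.isfinite(series)
        out = np.full(T, np.nan)
        if ok.sum() < 4:
            return out
        s, e = np.flatnonzero(ok)[0], np.flatnonzero(ok)[-1] + 1
        seg = np.where(np.isfinite(series[s:e]), series[s:e], np.nanmean(series[s:e]))
        det = sinc_detrend(seg, cutoff_period=cutoff_period, dt=dt)
        ridge = extract_ridge(morlet_spectrum(det, periods=periods, dt=dt))
        out[s:e] = ridge.period
        return out

    prox_P = ridge_periods(proximal)
    dist_P = ridge_periods(distal)
    in_window = (t_rel > window_min[0]) & (t_rel <= window_min[1])
    prox_samples = prox_P[in_window & np.isfinite(prox_P)]
    dist_samples = dist_P[in_window & np.isfinite(dist_P)]
    return PeriodGradient(
        times=t_rel,
        proximal_period=prox_P,
        distal_period=dist_P,
        in_window=in_window,
        proximal_samples=prox_samples,
        distal_samples=dist_samples,
        proximal=_summary(prox_samples),
        distal=_summary(dist_samples),
        window_min=(float(window_min[0]), float(window_min[1])),
        side=side,
    )
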