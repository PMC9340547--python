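"""Wavelet phase and period extraction from oscillatory time series.

Each kymograph row is a reporter time series carrying one oscillator's
history.  Analysis proceeds in three steps:

1. **Sinc detrending** — a windowed-sinc low-pass estimate of the slow
   trend (cut-off period 220 min by default, well above the oscillation
   band) is subtracted, removing the pulse envelope and photobleaching
   drift without touching oscillation phase.
2. **Continuous Morlet transform** — the detrended series is convolved
   with complex Morlet wavelets over a dense period grid (600 periods,
   100–220 min by default).  With central frequency ω₀ = 2π the wavelet
   scale coincides with the Fourier period, and the per-scale amplitude
   normalisation makes a unit-amplitude sinusoid at a grid period produce
   ridge power 1 away from the series ends.
3. **Ridge tracing** — the per-time power maximum across periods yields
   the instantaneous period, and the complex coefficient there supplies
   the instantaneous phase (cosine convention: phase 0 at an oscillation
   maximum) and power.

Edge effects are quantified by the cone of influence (one wavelet
e-folding time from either end) and reported, not masked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .loi import Kymograph

__all__ = [
    "WaveletSpectrum",
    "Ridge",
    "PhaseKymograph",
    "sinc_detrend",
    "morlet_spectrum",
    "extract_ridge",
    "make_phase_kymograph",
    "default_period_grid",
    "DEFAULT_CUTOFF_PERIOD",
    "DEFAULT_N_PERIODS",
    "DEFAULT_PERIOD_RANGE",
    "DEFAULT_PHASE_SIGMA_PX",
    "MORLET_OMEGA0",
    "SINC_HALFWIDTH_FACTOR",
]

#: Low-pass cut-off period of the detrending filter (min).
DEFAULT_CUTOFF_PERIOD = 220.0
#: Size and span of the wavelet period grid (min).
DEFAULT_N_PERIODS = 600
DEFAULT_PERIOD_RANGE = (100.0, 220.0)
#: Spatial Gaussian applied across kymograph rows before phase extraction.
DEFAULT_PHASE_SIGMA_PX = 5.0
#: Morlet central angular frequency; 2π makes scale equal Fourier period.
MORLET_OMEGA0 = 2.0 * np.pi
#: Sinc kernel half-width as a multiple of the cut-off period.  Three
#: cut-off periods keep the transition band narrow enough that a 150-min
#: oscillation passes the detrender with <5% amplitude loss.
SINC_HALFWIDTH_FACTOR = 3.0
#: Wavelet truncation radius in units of the Gaussian envelope width.
_TRUNCATION_SIGMAS = 4.0


def default_period_grid(
    n_periods: int = DEFAULT_N_PERIODS,
    period_range: tuple[float, float] = DEFAULT_PERIOD_RANGE,
) -> np.ndarray:
    return np.linspace(period_range[0], period_range[1], n_periods)


def _mirror_pad(x: np.ndarray, pad: int) -> np.ndarray:
    """Mirror-extend a series (no edge repetition), tiling for long pads."""
    out = x
    remaining = int(pad)
    while remaining > 0:
        p = min(remaining, out.size - 1)
        if p == 0:  # pragma: no cover - length-1 series
            return np.full(x.size + 2 * pad, x[0])
        out = np.pad(out, p, mode="reflect")
        remaining -= p
    return out


def sinc_detrend(
    series: np.ndarray,
    cutoff_period: float = DEFAULT_CUTOFF_PERIOD,
    dt: float = 1.0,
    halfwidth_factor: float = SINC_HALFWIDTH_FACTOR,
) -> np.ndarray:
    """Remove the slow trend with a Blackman-windowed sinc low-pass filter.

    The trend is the convolution of the series with a unit-gain FIR low-pass
    kernel; the detrended series is the difference.  ``cutoff_period`` marks
    the *passband edge* of the oscillation band: components faster than the
    cut-off survive detrending with unit gain, and the filter's transition
    band lies entirely at slower periods (so oscillations right at the edge
    of the analysis band are neither attenuated nor period-shifted).
    Boundaries are mirror-extended.  Operates along the last axis of 1D or
    2D input.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    if n < 2:
        raise ValueError("series too short to detrend (need at least 2 samples)")
    hw = int(round(halfwidth_factor * cutoff_period / dt))
    k = np.arange(-hw, hw + 1)
    n_taps = 2 * hw + 1
    # shift the design frequency down by the Blackman half transition width
    # so the stopband-to-passband transition ends at 1/cutoff_period
    fc = max(dt / cutoff_period - 2.75 / n_taps, 1e-9)
    kernel = 2.0 * fc * np.sinc(2.0 * fc * k) * np.blackman(n_taps)
    kernel /= kernel.sum()
    if x.ndim == 1:
        trend = np.convolve(_mirror_pad(x, hw), kernel, mode="valid")
    elif x.ndim == 2:
        trend = np.stack([np.convolve(_mirror_pad(row, hw), kernel, mode="valid") for row in x])
    else:
        raise ValueError("series must be 1D or 2D")
    return x - trend


@dataclass
class WaveletSpectrum:
    """Complex Morlet coefficients over a period grid.

    ``coefficients`` has shape ``(n_periods, T)``; magnitudes are amplitude
    normalised (a unit sinusoid at a grid period gives magnitude 1 at that
    period, away from the edges).
    """

    coefficients: np.ndarray
    periods: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.periods = np.asarray(self.periods, dtype=float)
        if np.any(np.diff(self.periods) <= 0):
            raise ValueError("period grid must be strictly increasing")
        if self.coefficients.shape[0] != self.periods.size:
            raise ValueError("coefficient rows must match the period grid")

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    def cone_of_influence(self) -> np.ndarray:
        """Boolean (n_periods, T) mask, True where edge effects are small.

        A period is trusted at times further than one wavelet e-folding
        time (√2 × scale) from both series ends.
        """
        T = self.coefficients.shape[1]
        t = self.dt * np.arange(T)
        dist = np.minimum(t, t[::-1])
        scales = self.periods * MORLET_OMEGA0 / (2.0 * np.pi)
        return dist[None, :] >= np.sqrt(2.0) * scales[:, None]


def morlet_spectrum(
    series: np.ndarray,
    periods: np.ndarray | None = None,
    dt: float = 1.0,
    omega0: float = MORLET_OMEGA0,
) -> WaveletSpectrum:
    """Continuous wavelet transform with complex Morlet wavelets.

    ``periods`` defaults to the 600-point grid spanning 100–220 min.  All
    grid periods must exceed the Nyquist period ``2 dt``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1D")
    if periods is None:
        periods = default_period_grid()
    periods = np.asarray(periods, dtype=float)
    if np.any(periods <= 2.0 * dt):
        raise ValueError(f"period grid must stay above the Nyquist period {2.0 * dt} min")
    if np.any(np.diff(periods) <= 0):
        raise ValueError("period grid must be strictly increasing")
    n = x.size
    scales = periods * omega0 / (2.0 * np.pi)
    hw_max = int(np.ceil(_TRUNCATION_SIGMAS * scales.max() / dt))
    # zero-extended boundaries: beyond the series ends the signal is taken
    # as absent, which attenuates edge coefficients without injecting the
    # spurious interference a mirrored oscillation would
    nfft = int(2 ** np.ceil(np.log2(n + 2 * hw_max + 1)))
    xf = np.fft.fft(x, nfft)
    k = dt * np.arange(-hw_max, hw_max + 1)
    arg = k[None, :] / scales[:, None]
    envelope = np.exp(-0.5 * arg**2)
    envelope[np.abs(arg) > _TRUNCATION_SIGMAS] = 0.0
    kernels = envelope * np.exp(1j * omega0 * arg)
    norms = 2.0 / envelope.sum(axis=1)
    # correlation with the conjugate wavelet, evaluated via FFT; the kernel
    # index k maps sample n+k, so conjugate-reverse before convolving
    kf = np.fft.fft(np.conj(kernels[:, ::-1]), nfft, axis=1)
    conv = np.fft.ifft(xf[None, :] * kf, axis=1)
    coeffs = conv[:, hw_max : hw_max + n] * norms[:, None]
    return WaveletSpectrum(coefficients=coeffs, periods=periods, dt=dt)


@dataclass
class Ridge:
    """Power-maximum trace through a wavelet spectrum.

    Per time point: instantaneous period (on the grid), phase in (−π, π]
    with 0 at an oscillation maximum, normalised power, and a validity
    flag (power at or above the extraction threshold).
    """

    period: np.ndarray
    phase: np.ndarray
    power: np.ndarray
    valid: np.ndarray
    dt: float

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.period.size)


def _wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap to (−π, π]."""
    out = np.angle(np.exp(1j * phi)) if not np.iscomplexobj(phi) else np.angle(phi)
    return np.where(out <= -np.pi, np.pi, out)


def extract_ridge(spectrum: WaveletSpectrum, power_threshold: float = 0.0) -> Ridge:
    """Trace the per-time power maximum and read phase and power along it.

    Ties break toward the smaller period.  Points whose ridge power falls
    below ``power_threshold`` are flagged invalid (the default threshold 0
    keeps everything).
    """
    power = spectrum.power
    idx = np.argmax(power, axis=0)
    cols = np.arange(power.shape[1])
    coef = spectrum.coefficients[idx, cols]
    pw = power[idx, cols]
    phase = _wrap_phase(np.angle(coef))
    valid = pw >= power_threshold
    return Ridge(period=spectrum.periods[idx], phase=phase, power=pw, valid=valid, dt=spectrum.dt)


@dataclass
class PhaseKymograph:
    """Wrapped-phase matrix restacked from per-row ridges.

    Columns start at the manually determined oscillation-onset frame of the
    source kymograph (earlier frames are cropped).  ``period`` and
    ``power`` carry the per-cell ridge period and power alongside the
    phase.  Invalid cells hold NaN.
    """

    phase: np.ndarray
    period: np.ndarray
    power: np.ndarray
    valid: np.ndarray
    onset_frame: int
    midline_row: int
    spatial_pixel: float
    dt: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        ok = self.valid
        ph = self.phase[ok]
        if ph.size and (np.any(ph <= -np.pi) or np.any(ph > np.pi)):
            raise ValueError("valid phases must lie in (-pi, pi]")

    @property
    def n_rows(self) -> int:
        return self.phase.shape[0]

    @property
    def n_frames(self) -> int:
        return self.phase.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Time since onset, per column (min)."""
        return self.dt * np.arange(self.n_frames)

    def half(self, side: str = "left") -> tuple[np.ndarray, np.ndarray]:
        """Phases of one side ordered midline → distal (row 0 = midline)."""
        if side == "left":
            sl = slice(self.midline_row, None, -1)
        elif side == "right":
            sl = slice(self.midline_row, None)
        else:
            raise ValueError("side must be 'left' or 'right'")
        return self.phase[sl], self.valid[sl]


def _masked_gaussian_rows(data: np.ndarray, valid: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian smoothing along rows that ignores invalid cells.

    Normalised convolution: the mask acts as per-cell weight, so valid
    cells near the moving domain boundary are not contaminated by the
    fill value.
    """
    if sigma <= 0:
        return data.copy()
    w = valid.astype(float)
    num = ndimage.gaussian_filter1d(data * w, sigma, axis=0, mode="nearest")
    den = ndimage.gaussian_filter1d(w, sigma, axis=0, mode="nearest")
    out = data.copy()
    inside = den > 1e-12
    np.divide(num, den, out=out, where=inside & valid)
    return np.where(valid, out, data)


def make_phase_kymograph(
    kymo: Kymograph,
    onset_frame: int,
    spatial_sigma_px: float = DEFAULT_PHASE_SIGMA_PX,
    cutoff_period: float = DEFAULT_CUTOFF_PERIOD,
    periods: np.ndarray | None = None,
    power_threshold: float = 0.0,
    min_valid_samples: int | None = None,
) -> PhaseKymograph:
    """Turn an intensity kymograph into a phase kymograph.

    Frames before ``onset_frame`` are cropped, the matrix is smoothed
    across rows (masked Gaussian), and every row's valid stretch is
    detrended, wavelet transformed and ridge-extracted.  The wrapped ridge
    phases are restacked row-wise; rows whose valid stretch is shorter
    than ``min_valid_samples`` (default: two cycles of the fastest grid
    period) stay invalid throughout.
    """
    if not 0 <= onset_frame < kymo.n_frames:
        raise ValueError(f"onset frame {onset_frame} outside the kymograph")
    if periods is None:
        periods = default_period_grid()
    dt = kymo.dt
    if min_valid_samples is None:
        min_valid_samples = max(4, int(np.ceil(2.0 * periods[0] / dt)))
    data = kymo.data[:, onset_frame:]
    valid = kymo.valid[:, onset_frame:]
    T = data.shape[1]
    if T < min_valid_samples:
        raise ValueError(
            f"only {T} frames remain after cropping at onset {onset_frame}; "
            f"need at least {min_valid_samples}"
        )
    smoothed = _masked_gaussian_rows(data, valid, spatial_sigma_px)
    nrows = data.shape[0]
    phase = np.full((nrows, T), np.nan)
    period = np.full((nrows, T), np.nan)
    power = np.full((nrows, T), np.nan)
    out_valid = np.zeros((nrows, T), dtype=bool)
    for r in range(nrows):
        vr = valid[r]
        if not vr.any():
            continue
        # longest contiguous valid stretch of this row
        edges = np.flatnonzero(np.diff(np.concatenate([[0], vr.view(np.int8), [0]])))
        starts, ends = edges[::2], edges[1::2]
        k = int(np.argmax(ends - starts))
        s, e = int(starts[k]), int(ends[k])
        if e - s < min_valid_samples:
            continue
        seg = smoothed[r, s:e]
        det = sinc_detrend(seg, cutoff_period=cutoff_period, dt=dt)
        ridge = extract_ridge(morlet_spectrum(det, periods=periods, dt=dt), power_threshold)
        phase[r, s:e] = ridge.phase
        period[r, s:e] = ridge.period
        power[r, s:e] = ridge.power
        out_valid[r, s:e] = ridge.valid
    phase[~out_valid] = np.nan
    period[~out_valid] = np.nan
    power[~out_valid] = np.nan
    return PhaseKymograph(
        phase=phase, period=period, power=power, valid=out_valid,
        onset_frame=int(onset_frame), midline_row=kymo.midline_row,
        spatial_pixel=kymo.spatial_pixel, dt=dt,
        start_time=kymo.start_time + onset_frame * dt,
    )
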