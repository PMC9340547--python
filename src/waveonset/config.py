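"""Pipeline configuration: defaults, YAML parsing, validation.

Every stage default named across the package is gathered here so a single
structured-text file drives a full run.  Unknown keys are rejected, units
are documented per field, and cross-field constraints (wavelet grid vs
Nyquist, detrend cut-off vs grid span) are enforced at load time.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "PreprocessConfig", "LoiConfig", "PhaseConfig",
           "StatsConfig", "FlowConfig", "validate_config", "load_config"]


@dataclass
class PreprocessConfig:
    background_box: list | None = None  # ((z0,z1),(y0,y1),(x0,x1)) voxels; corner box if None
    background_offset: float = 1000.0   # counts added back after subtraction
    mask_threshold: float = 1030.0      # counts, summed-mask binarisation
    z_factor: float = 1.0               # Z resampling; 3.59 for the native anisotropic grid
    subsample_xy: float = 1.0           # lateral block-mean factor (3.75 for raw camera frames)
    rotation_angles: list = field(default_factory=lambda: [0.0, 0.0, 0.0])  # degrees about COM
    register: bool = True               # recursive frame-to-frame registration
    reference_index: int = 0


@dataclass
class LoiConfig:
    n_segments: int = 100_000           # chords in the arc-length table
    smoothing_sigma_px: float = 6.0     # 3D Gaussian before surface sampling (≈12.5 μm)
    sphere_diameter_px: float = 12.0    # spherical averaging volume (≈25 μm)
    time_smoothing: float | None = None  # intermediate-anchor spline stiffness


@dataclass
class PhaseConfig:
    onset_frame: int | None = None      # manual onset; None = take from phantom ground truth
    fill_value: float = 1067.0          # counts, out-of-domain kymograph cells
    spatial_sigma_px: float = 5.0       # Gaussian across rows (≈10.4 μm)
    cutoff_period: float = 220.0        # sinc detrend cut-off (min)
    n_periods: int = 600
    period_min: float = 100.0           # wavelet grid span (min)
    period_max: float = 220.0
    power_threshold: float = 0.0


@dataclass
class StatsConfig:
    distal_crop_px: int = 20            # cropped from each phase column's distal end
    distal_shift_px: int = 20           # boundary-contour inward shift (≈41.8 μm)
    corridor_px: int = 8                # corridor width for period series (≈16.7 μm)
    window_min: list = field(default_factory=lambda: [120.0, 360.0])  # 2–6 h after onset
    side: str = "left"


@dataclass
class FlowConfig:
    enabled: bool = True
    radius_um: float = 30.0             # LOI proximity radius
    min_consecutive_min: float = 300.0  # continuous residence requirement
    pulse_to_onset_min: float = 260.0   # t=0 definition relative to the pulse peak
    bin_um: float = 25.0                # vector-field grid spacing


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "waveonset_out"
    save_volumes: bool = False          # write TIFF stacks of generated/processed volumes
    phantom: dict | None = None         # PhantomSpec overrides; None disables the synth stage
    input_volumes: str | None = None    # path to a volume manifest dir or TIFF stack
    input_landmarks: str | None = None
    input_tracks: str | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    loi: LoiConfig = field(default_factory=LoiConfig)
    phase: PhaseConfig = field(default_factory=PhaseConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    flow: FlowConfig = field(default_factory=FlowConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "loi": LoiConfig,
    "phase": PhaseConfig,
    "stats": StatsConfig,
    "flow": FlowConfig,
}


def _build_section(cls, payload: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    return cls(**payload)


def validate_config(raw: dict | str | None) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from YAML text or a dict.

    Missing sections take their documented defaults; an empty document
    yields the full-default configuration (phantom mode).  Violations are
    reported with the offending field name.
    """
    if raw is None:
        payload = {}
    elif isinstance(raw, str):
        payload = yaml.safe_load(raw) or {}
    else:
        payload = dict(raw)
    if not isinstance(payload, dict):
        raise ValueError("configuration root must be a mapping")
    top_known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(payload) - top_known
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in payload.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValueError(f"section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTIONS[key], value, key)
        else:
            kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    if cfg.phantom is None and not payload:
        cfg.phantom = {}  # empty file: self-contained phantom mode
    _cross_check(cfg)
    return cfg


def _cross_check(cfg: PipelineConfig) -> None:
    ph = cfg.phase
    if ph.period_min <= 0 or ph.period_max <= ph.period_min:
        raise ValueError("phase.period_min/period_max must satisfy 0 < min < max")
    dt = None
    if cfg.phantom is not None:
        dt = cfg.phantom.get("frame_interval_dt", 10.0)
        if dt <= 0:
            raise ValueError("phantom.frame_interval_dt must be positive")
        if ph.period_min <= 2.0 * dt:
            raise ValueError(
                f"wavelet grid floor {ph.period_min} min is at or below the Nyquist period "
                f"{2.0 * dt} min for dt={dt} min"
            )
    if ph.cutoff_period < ph.period_max:
        warnings.warn(
            f"detrend cut-off {ph.cutoff_period} min lies below the top of the wavelet grid "
            f"({ph.period_max} min); the trend filter will attenuate the slow end of the "
            "analysis band",
            RuntimeWarning,
            stacklevel=2,
        )
    if cfg.stats.side not in ("left", "right"):
        raise ValueError("stats.side must be 'left' or 'right'")
    w = cfg.stats.window_min
    if len(w) != 2 or w[0] >= w[1] or w[0] < 0:
        raise ValueError("stats.window_min must be an increasing non-negative pair")
    if cfg.flow.radius_um <= 0 or cfg.flow.min_consecutive_min < 0:
        raise ValueError("flow.radius_um must be positive and min_consecutive_min non-negative")


def load_config(path) -> PipelineConfig:
    return validate_config(Path(path).read_text())
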