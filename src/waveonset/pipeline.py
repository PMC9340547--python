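"""End-to-end orchestration: phantom → preprocessing → LOI → phase → statistics.

``run_pipeline`` executes the full quantification chain and writes every
intermediate (kymograph, phase kymograph, ridge matrices, statistics
tables) plus a provenance sidecar echoing the configuration and seed, so
any stage can be re-run bit-identically from its inputs.  Stage failures
abort with the stage name; partial outputs are retained.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .flow import VectorField, align_track_time, average_vector_field, filter_tracks_by_path
from .loi import (
    Kymograph,
    LandmarkSet,
    SurfacePath,
    build_surface_path,
    interpolate_landmarks,
    locate_intermediate_point,
    sample_surface_kymograph,
)
from .preprocess import (
    VolumeSeries,
    align_by_mask_com,
    register_recursive,
    resample_isotropic,
    subsample_xy,
    subtract_temporal_background,
)
from .spectral import PhaseKymograph, default_period_grid, make_phase_kymograph
from .synth import GroundTruth, PhantomSpec, generate_phantom_tracks, generate_phantom_volume
from .wavestats import PeriodGradient, WaveStatSeries, compute_wave_stats, sample_period_gradient
from . import io as wio

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    config: PipelineConfig
    kymograph: Kymograph
    phase_kymograph: PhaseKymograph
    wave_stats: WaveStatSeries
    period_gradient: PeriodGradient
    flow_field: VectorField | None
    ground_truth: GroundTruth | None
    onset_frame: int
    output_dir: Path


class _Stage:
    """Context manager attributing failures to a named stage."""

    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        if exc is not None:
            raise RuntimeError(f"stage '{self.name}' failed: {exc}") from exc
        logger.info("stage %s: done", self.name)
        return False


def _phantom_spec(cfg: PipelineConfig) -> PhantomSpec:
    overrides = dict(cfg.phantom or {})
    overrides.setdefault("rng_seed", cfg.seed)
    if "volume_shape" in overrides:
        overrides["volume_shape"] = tuple(overrides["volume_shape"])
    return PhantomSpec(**overrides)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute synth (optional) → preprocess → loi → phase → stats (+ flow)."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.phantom is None and cfg.phase.onset_frame is None:
        raise ValueError("phase.onset_frame is required when no phantom ground truth is available")
    if cfg.phantom is None and cfg.input_volumes is None:
        raise ValueError("either a phantom section or input_volumes must be configured")

    ground_truth: GroundTruth | None = None
    tracks = None
    with _Stage("synth"):
        if cfg.phantom is not None:
            spec = _phantom_spec(cfg)
            vol, landmarks, ground_truth = generate_phantom_volume(spec)
            if cfg.flow.enabled:
                tracks, gt_tracks = generate_phantom_tracks(spec)
                ground_truth.track_speeds = gt_tracks.track_speeds
                wio.write_tracks(tracks, out / "tracks.csv")
            wio.write_landmarks(landmarks, out / "landmarks.csv")
            (out / "ground_truth.json").write_text(ground_truth.to_json() + "\n")
            if cfg.save_volumes:
                wio.write_volume_series(vol, out / "phantom_volume")
        else:
            vol = wio.read_volume_series(cfg.input_volumes)
            landmarks = wio.read_landmarks(cfg.input_landmarks)
            if cfg.flow.enabled and cfg.input_tracks:
                tracks = wio.read_tracks(cfg.input_tracks)

    pp = cfg.preprocess
    with _Stage("preprocess"):
        if pp.subsample_xy != 1.0:
            vol = subsample_xy(vol, pp.subsample_xy)
        vol = subtract_temporal_background(vol, pp.background_box, pp.background_offset)
        if pp.register:
            vol, shifts = register_recursive(
                vol, reference_index=pp.reference_index, fill_value=pp.background_offset
            )
            landmarks = _shift_landmarks(landmarks, shifts, vol)
        angles = landmarks.rotation_angles if any(landmarks.rotation_angles) else tuple(pp.rotation_angles)
        vol, alignment = align_by_mask_com(
            vol, pp.mask_threshold, angles, fill_value=pp.background_offset
        )
        landmarks = landmarks.transform(alignment.apply_to_points)
        if pp.z_factor != 1.0:
            vol = resample_isotropic(vol, pp.z_factor)
        if cfg.save_volumes:
            wio.write_volume_series(vol, out / "preprocessed_volume")

    with _Stage("loi"):
        frames = interpolate_landmarks(landmarks, vol.times)
        com = vol.center_um()
        left_paths, right_paths = [], []
        for name, store in (("left_distal", left_paths), ("right_distal", right_paths)):
            distal = getattr(frames, name)
            inter = locate_intermediate_point(
                vol, com, frames.origin, distal, time_smoothing=cfg.loi.time_smoothing
            )
            for t in range(vol.n_frames):
                store.append(
                    build_surface_path(
                        frames.origin[t], inter[t], distal[t], n_segments=cfg.loi.n_segments
                    )
                )
        kym = sample_surface_kymograph(
            vol,
            left_paths,
            right_paths,
            smoothing_sigma_px=cfg.loi.smoothing_sigma_px,
            sphere_diameter_px=cfg.loi.sphere_diameter_px,
            fill_value=cfg.phase.fill_value,
        )
        wio.write_kymograph(kym, out / "kymograph.csv")
    path_times = vol.times
    del vol  # volumes are no longer needed; free the memory

    with _Stage("phase"):
        onset_frame = cfg.phase.onset_frame
        if onset_frame is None:
            onset_frame = int(round(ground_truth.onset_time / kym.dt))
        periods = default_period_grid(cfg.phase.n_periods, (cfg.phase.period_min, cfg.phase.period_max))
        pk = make_phase_kymograph(
            kym,
            onset_frame,
            spatial_sigma_px=cfg.phase.spatial_sigma_px,
            cutoff_period=cfg.phase.cutoff_period,
            periods=periods,
            power_threshold=cfg.phase.power_threshold,
        )
        wio.write_phase_kymograph(pk, out / "phase_kymograph.csv")

    with _Stage("stats"):
        stats = compute_wave_stats(pk, cfg.stats.distal_crop_px, cfg.stats.side)
        gradient = sample_period_gradient(
            kym,
            onset_frame,
            window_min=tuple(cfg.stats.window_min),
            distal_shift_px=cfg.stats.distal_shift_px,
            corridor_px=cfg.stats.corridor_px,
            side=cfg.stats.side,
            cutoff_period=cfg.phase.cutoff_period,
            periods=periods,
        )
        _write_stats(out, stats, gradient)

    field = None
    if cfg.flow.enabled and tracks:
        with _Stage("flow"):
            pulse_peak = (
                ground_truth.spec.pulse_peak_time if ground_truth is not None else 0.0
            )
            aligned = align_track_time(tracks, pulse_peak, cfg.flow.pulse_to_onset_min)
            t_shift = -(pulse_peak + cfg.flow.pulse_to_onset_min)
            kept, log = filter_tracks_by_path(
                aligned,
                path_times + t_shift,
                [[l, r] for l, r in zip(left_paths, right_paths)],
                radius_um=cfg.flow.radius_um,
                min_consecutive_min=cfg.flow.min_consecutive_min,
            )
            reference = left_paths[min(onset_frame, len(left_paths) - 1)]
            field = average_vector_field(kept, reference, bin_um=cfg.flow.bin_um)
            wio.write_tracks(kept, out / "tracks_selected.csv")
            _write_field(out / "flow_field.csv", field)

    _write_provenance(out, cfg, onset_frame)
    return PipelineResult(
        config=cfg,
        kymograph=kym,
        phase_kymograph=pk,
        wave_stats=stats,
        period_gradient=gradient,
        flow_field=field,
        ground_truth=ground_truth,
        onset_frame=onset_frame,
        output_dir=out,
    )


def _shift_landmarks(lm: LandmarkSet, shifts, vol: VolumeSeries) -> LandmarkSet:
    """Apply per-frame registration shifts to keyframe landmarks (μm)."""
    spacing = np.array(vol.voxel_spacing)
    times = vol.times
    idx = np.clip(np.round((lm.times - vol.start_time) / vol.frame_interval).astype(int), 0, len(shifts) - 1)
    offsets = np.array([shifts[i] for i in idx], dtype=float) * spacing

    def move(points: np.ndarray) -> np.ndarray:
        return points + offsets

    return lm.transform(move)


def _write_stats(out: Path, stats: WaveStatSeries, gradient: PeriodGradient) -> None:
    pd.DataFrame(
        {
            "time_min": stats.times,
            "wave_number_q": stats.q,
            "mesoderm_length_um": stats.L,
            "phase_gradient_slope_per_um": stats.slope,
            "defined": stats.defined.astype(int),
        }
    ).to_csv(out / "wave_stats.csv", index=False, float_format="%.9g")
    pd.DataFrame(
        {
            "time_min": gradient.times,
            "proximal_period_min": gradient.proximal_period,
            "distal_period_min": gradient.distal_period,
            "in_window": gradient.in_window.astype(int),
        }
    ).to_csv(out / "period_gradient.csv", index=False, float_format="%.9g")
    wio.write_json(
        out / "summary.json",
        {
            "wave_number": stats.summary["wave_number"],
            "mesoderm_length": stats.summary["mesoderm_length"],
            "phase_gradient_slope": stats.summary["slope"],
            "proximal_period": gradient.proximal,
            "distal_period": gradient.distal,
            "period_difference_min": gradient.median_difference,
            "period_window_min": list(gradient.window_min),
            "side": gradient.side,
        },
    )


def _write_field(path: Path, field: VectorField) -> None:
    rows = []
    for i, s in enumerate(field.s_centers):
        for j, l in enumerate(field.lat_centers):
            rows.append(
                {
                    "arc_um": s,
                    "lateral_um": l,
                    "v_arc_um_min": field.mean_velocity[i, j, 0],
                    "v_lat_um_min": field.mean_velocity[i, j, 1],
                    "count": field.count[i, j],
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")


def _write_provenance(out: Path, cfg: PipelineConfig, onset_frame: int) -> None:
    wio.write_json(
        out / "provenance.json",
        {
            "package": "waveonset",
            "version": __version__,
            "config": cfg.to_dict(),
            "onset_frame_used": onset_frame,
        },
    )
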