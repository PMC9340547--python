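"""File formats: TIFF volumes, CSV tables, JSON sidecars.

Volumes are written as one multi-page TIFF per frame with a JSON manifest
(single-stack files are also read).  Kymographs, ridges, landmarks, tracks
and statistics travel as plain CSV with a JSON sidecar carrying the
calibration (spatial pixel, frame interval, midline row, fill value, …),
so every statistic can be recomputed without image decoding.

Point coordinates in files are (x, y, z) μm columns; in memory they are
(z, y, x) arrays matching the voxel axes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flow import CellTrack
from .loi import Kymograph, LandmarkSet
from .preprocess import VolumeSeries
from .spectral import PhaseKymograph

__all__ = [
    "write_volume_series",
    "read_volume_series",
    "write_landmarks",
    "read_landmarks",
    "write_tracks",
    "read_tracks",
    "write_kymograph",
    "read_kymograph",
    "write_phase_kymograph",
    "write_json",
    "read_json",
]

_FLOAT_FMT = "%.9g"


def write_json(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# volumes


def write_volume_series(vol: VolumeSeries, directory, prefix: str = "frame", dtype=np.uint16) -> Path:
    """File-per-frame TIFF stack with a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for t in range(vol.n_frames):
        name = f"{prefix}_{t:04d}.tif"
        frame = vol.data[t]
        if np.issubdtype(dtype, np.integer):
            info = np.iinfo(dtype)
            frame = np.clip(np.round(frame), info.min, info.max)
        tifffile.imwrite(directory / name, frame.astype(dtype))
        names.append(name)
    write_json(
        directory / "manifest.json",
        {
            "frames": names,
            "voxel_spacing_um": list(vol.voxel_spacing),
            "frame_interval_min": vol.frame_interval,
            "start_time_min": vol.start_time,
            "axis_order": "ZYX",
        },
    )
    return directory


def read_volume_series(source) -> VolumeSeries:
    """Read a manifest directory or a single multi-page TIFF stack."""
    source = Path(source)
    if source.is_dir():
        manifest = read_json(source / "manifest.json")
        frames = [tifffile.imread(source / n) for n in manifest["frames"]]
        return VolumeSeries(
            data=np.stack(frames).astype(np.float32),
            voxel_spacing=tuple(manifest["voxel_spacing_um"]),
            frame_interval=manifest["frame_interval_min"],
            start_time=manifest.get("start_time_min", 0.0),
        )
    data = tifffile.imread(source).astype(np.float32)
    if data.ndim != 4:
        raise ValueError(f"expected a T×Z×Y×X stack in {source}, got shape {data.shape}")
    sidecar = source.with_suffix(".json")
    meta = read_json(sidecar) if sidecar.exists() else {}
    return VolumeSeries(
        data=data,
        voxel_spacing=tuple(meta.get("voxel_spacing_um", (1.0, 1.0, 1.0))),
        frame_interval=meta.get("frame_interval_min", 1.0),
        start_time=meta.get("start_time_min", 0.0),
    )


# ---------------------------------------------------------------------------
# landmarks and tracks


def write_landmarks(lm: LandmarkSet, path) -> Path:
    path = Path(path)
    rows = []
    for name in ("origin", "left_distal", "right_distal"):
        arr = getattr(lm, name)
        for t, (z, y, x) in zip(lm.times, arr):
            rows.append({"time_min": t, "landmark": name, "x_um": x, "y_um": y, "z_um": z})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")
    write_json(path.with_suffix(".json"), {"rotation_angles_deg": list(lm.rotation_angles)})
    return path


def read_landmarks(path) -> LandmarkSet:
    path = Path(path)
    df = pd.read_csv(path)
    times = np.sort(df["time_min"].unique())
    anchors = {}
    for name in ("origin", "left_distal", "right_distal"):
        sub = df[df["landmark"] == name].set_index("time_min").loc[times]
        anchors[name] = sub[["z_um", "y_um", "x_um"]].to_numpy(dtype=float)
    sidecar = path.with_suffix(".json")
    rotation = tuple(read_json(sidecar).get("rotation_angles_deg", (0.0, 0.0, 0.0))) if sidecar.exists() else (0.0, 0.0, 0.0)
    return LandmarkSet(times=times, rotation_angles=rotation, **anchors)


def write_tracks(tracks, path) -> Path:
    path = Path(path)
    frames = []
    for tr in tracks:
        frames.append(
            pd.DataFrame(
                {
                    "track_id": tr.track_id,
                    "t_min": tr.times,
                    "x_um": tr.positions[:, 2],
                    "y_um": tr.positions[:, 1],
                    "z_um": tr.positions[:, 0],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["track_id", "t_min", "x_um", "y_um", "z_um"]
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


def read_tracks(path) -> list[CellTrack]:
    df = pd.read_csv(path)
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("t_min")
        tracks.append(
            CellTrack(
                track_id=int(tid),
                times=sub["t_min"].to_numpy(dtype=float),
                positions=sub[["z_um", "y_um", "x_um"]].to_numpy(dtype=float),
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# kymographs


def write_kymograph(kym: Kymograph, path) -> Path:
    path = Path(path)
    np.savetxt(path, kym.data, delimiter=",", fmt=_FLOAT_FMT)
    write_json(
        path.with_suffix(".json"),
        {
            "kind": "intensity",
            "spatial_pixel_um": kym.spatial_pixel,
            "frame_interval_min": kym.dt,
            "start_time_min": kym.start_time,
            "midline_row": kym.midline_row,
            "fill_value": kym.fill_value,
            "sides": {"above_midline": "left", "below_midline": "right"},
        },
    )
    return path


def read_kymograph(path) -> Kymograph:
    path = Path(path)
    data = np.loadtxt(path, delimiter=",", ndmin=2)
    meta = read_json(path.with_suffix(".json"))
    fill = meta["fill_value"]
    valid = ~np.isclose(data, fill) if not np.isnan(fill) else ~np.isnan(data)
    return Kymograph(
        data=np.where(valid, data, fill),
        valid=valid,
        midline_row=meta["midline_row"],
        spatial_pixel=meta["spatial_pixel_um"],
        dt=meta["frame_interval_min"],
        start_time=meta.get("start_time_min", 0.0),
        fill_value=fill,
    )


def write_phase_kymograph(pk: PhaseKymograph, path) -> Path:
    """Phase kymograph in the kymograph CSV format with a phase flag.

    Three matrices are written: phase (``<stem>.csv``), ridge period and
    ridge power (suffixes ``_period`` / ``_power``); invalid cells are NaN.
    """
    path = Path(path)
    np.savetxt(path, pk.phase, delimiter=",", fmt=_FLOAT_FMT)
    np.savetxt(path.with_name(path.stem + "_period.csv"), pk.period, delimiter=",", fmt=_FLOAT_FMT)
    np.savetxt(path.with_name(path.stem + "_power.csv"), pk.power, delimiter=",", fmt=_FLOAT_FMT)
    write_json(
        path.with_suffix(".json"),
        {
            "kind": "phase",
            "spatial_pixel_um": pk.spatial_pixel,
            "frame_interval_min": pk.dt,
            "start_time_min": pk.start_time,
            "midline_row": pk.midline_row,
            "onset_frame": pk.onset_frame,
            "fill_value": float("nan"),
            "phase_range": "(-pi, pi]",
        },
    )
    return path
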