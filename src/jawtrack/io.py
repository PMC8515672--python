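"""Readers and writers for all interchange formats.

Fixed CSV dialect: comma separator, ``.`` decimal point, UTF-8, one header
row.  Marker files are long-format (frame, time_ms, label, x_mm, y_mm,
z_mm); EMG files are wide (time_ms + one µV column per channel); meshes go
through trimesh (STL/PLY, ASCII and binary).  All coordinates are mm.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import trimesh
import yaml

from .core import CaptureSequence, LabeledPointSet
from .emg import BurstSet, EMGRecord
from .errors import InputError, ParseError
from .integration import Trajectory
from .occlusion import OcclusionSeries
from .phases import PhaseSegmentation

MARKER_COLUMNS = ["frame", "time_ms", "label", "x_mm", "y_mm", "z_mm"]


# ---------------------------------------------------------------------------
# markers
# ---------------------------------------------------------------------------

def write_markers(capture: CaptureSequence, path: str | Path) -> None:
    rows = []
    for i, frame in enumerate(capture.frames):
        fid = frame.frame_id if frame.frame_id is not None else i
        t = fid * 1000.0 / capture.frame_rate
        for label, p in zip(frame.labels, frame.points):
            rows.append((fid, t, label, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=MARKER_COLUMNS).to_csv(
        path, index=False, encoding="utf-8")


def read_markers(path: str | Path,
                 frame_rate: float | None = None) -> CaptureSequence:
    """Read a long-format marker CSV.

    The frame rate is taken from the time_ms column spacing unless given
    explicitly.  Malformed rows raise :class:`ParseError` with 1-based
    file line numbers (header is line 1).
    """
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")
    bad_lines = []
    for col in ("frame", "time_ms", "x_mm", "y_mm", "z_mm"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()]
        bad_lines += [int(i) + 2 for i in bad]  # +2: header + 0-base
        df[col] = vals
    if bad_lines:
        raise ParseError(
            f"{path}: non-numeric values at line(s) "
            f"{sorted(set(bad_lines))}")
    dup = df.duplicated(subset=["frame", "label"])
    if dup.any():
        lines = [int(i) + 2 for i in df.index[dup]]
        raise ParseError(f"{path}: duplicate (frame,label) at line(s) {lines}")
    if frame_rate is None:
        times = np.sort(df["time_ms"].unique())
        if len(times) < 2:
            raise ParseError(f"{path}: cannot infer frame rate from one frame")
        dt = float(np.median(np.diff(times)))
        frame_rate = 1000.0 / dt
    frames = []
    for fid, grp in df.groupby("frame", sort=True):
        frames.append(LabeledPointSet(
            tuple(grp["label"].astype(str)),
            grp[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
            frame_id=int(fid)))
    # unify label order across frames
    labels = frames[0].labels
    frames = [f if f.labels == labels else f.subset(labels) for f in frames]
    return CaptureSequence(frames, frame_rate)


def write_pointset(points: LabeledPointSet, path: str | Path) -> None:
    """Write a single labeled point set (e.g. marker reference, landmarks)."""
    pd.DataFrame({
        "label": points.labels,
        "x_mm": points.points[:, 0],
        "y_mm": points.points[:, 1],
        "z_mm": points.points[:, 2],
    }).to_csv(path, index=False, encoding="utf-8")


def read_pointset(path: str | Path) -> LabeledPointSet:
    df = pd.read_csv(path, encoding="utf-8")
    for col in ("label", "x_mm", "y_mm", "z_mm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column(s) {col}")
    return LabeledPointSet(tuple(df["label"].astype(str)),
                           df[["x_mm", "y_mm", "z_mm"]].to_numpy(float))


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------

def write_mesh(mesh: trimesh.Trimesh, path: str | Path,
               ascii_format: bool = False) -> None:
    """Write STL or PLY (format from the extension).  Units are mm."""
    if mesh is None or len(mesh.faces) == 0:
        raise InputError("refusing to write an empty mesh")
    suffix = Path(path).suffix.lower()
    if ascii_format and suffix == ".stl":
        mesh.export(str(path), file_type="stl_ascii")
    elif ascii_format and suffix == ".ply":
        mesh.export(str(path), encoding="ascii")
    else:
        mesh.export(str(path))


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    """Read an STL or PLY mesh (ASCII or binary).  Units are mm."""
    try:
        mesh = trimesh.load_mesh(str(path), process=False)
    except Exception as exc:
        raise ParseError(f"{path}: cannot parse mesh ({exc})") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ParseError(f"{path}: empty or non-triangular mesh")
    # STL stores three independent vertices per facet; merging the exact
    # duplicates restores shared vertices without moving any coordinate
    mesh.merge_vertices()
    if len(mesh.faces) == 0:
        raise ParseError(f"{path}: mesh has no non-degenerate faces")
    return mesh


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def write_emg(record: EMGRecord, path: str | Path) -> None:
    df = pd.DataFrame({"time_ms": record.times_ms})
    for name, sig in record.channels.items():
        df[name] = sig
    df.to_csv(path, index=False, encoding="utf-8")


def read_emg(path: str | Path, sync_offset_ms: float = 0.0) -> EMGRecord:
    df = pd.read_csv(path, encoding="utf-8")
    if "time_ms" not in df.columns:
        raise ParseError(f"{path}: missing column(s) time_ms")
    if df.shape[1] < 2:
        raise ParseError(f"{path}: no channel columns")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError(f"{path}: need >= 2 samples")
    fs = 1000.0 / float(np.median(np.diff(t)))
    channels = {c: df[c].to_numpy(dtype=float)
                for c in df.columns if c != "time_ms"}
    return EMGRecord(channels, fs, sync_offset_ms)


# ---------------------------------------------------------------------------
# derived results
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({
        "frame": np.arange(len(traj)),
        "time_ms": traj.times_ms,
        "landmark": traj.landmark,
        "x_mm": traj.points[:, 0],
        "y_mm": traj.points[:, 1],
        "z_mm": traj.points[:, 2],
    }).to_csv(path, index=False, encoding="utf-8")


def read_trajectory(path: str | Path) -> Trajectory:
    df = pd.read_csv(path, encoding="utf-8")
    for col in ("time_ms", "landmark", "x_mm", "y_mm", "z_mm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column(s) {col}")
    t = df["time_ms"].to_numpy(float)
    fs = 1000.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    return Trajectory(str(df["landmark"].iloc[0]),
                      df[["x_mm", "y_mm", "z_mm"]].to_numpy(float), fs)


def write_occlusion(series: OcclusionSeries, path: str | Path) -> None:
    n = len(series)
    pd.DataFrame({
        "frame": np.arange(n),
        "time_ms": np.arange(n) * 1000.0 / series.frame_rate,
        "clearance_mm": series.clearance_mm,
        "contact": series.contact.astype(int),
    }).to_csv(path, index=False, encoding="utf-8")


def dump_json(obj: Any, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    Path(path).write_text(
        json.dumps(_plain(obj), sort_keys=True, indent=2,
                   separators=(",", ": ")) + "\n",
        encoding="utf-8")


def _plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def segmentation_report(seg: PhaseSegmentation) -> dict:
    return {
        "landmark": seg.landmark,
        "frame_rate": seg.frame_rate,
        "cycles": [
            {
                "max_closing": c.max_closing,
                "most_anterior": c.most_anterior,
                "max_opening": c.max_opening,
                "most_posterior": c.most_posterior,
                "occlusal_start": c.occlusal_start,
                "cycle_end": c.cycle_end,
                "phases": {k: list(v) for k, v in c.phases.items()},
                "flags": c.flags,
            }
            for c in seg.cycles
        ],
    }


def burst_report(bursts: BurstSet, aligned: dict | None = None) -> dict:
    rep = {
        "params": bursts.params,
        "flags": bursts.flags,
        "bursts": {ch: [{"onset_ms": b.onset_ms, "offset_ms": b.offset_ms}
                        for b in bl]
                   for ch, bl in bursts.bursts.items()},
    }
    if aligned is not None:
        rep["aligned_frames"] = aligned
    return rep


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Paths and parameters of the full analysis pipeline."""

    markers_csv: str
    mandible_mesh: str
    maxilla_mesh: str
    marker_reference_csv: str
    landmarks_csv: str
    static_frame_csv: str
    emg_csv: str | None = None
    output_dir: str = "jawtrack_out"
    frame_rate: float | None = None
    contact_threshold_mm: float = 0.05
    occlusion_region: str = "all"
    landmark: str = "molar_cusp"
    emg_sync_offset_ms: float = 0.0
    emg_highpass_hz: float = 100.0
    emg_envelope_ms: float = 10.0
    emg_baseline_ms: float = 200.0
    emg_k_sd: float = 3.0
    emg_min_duration_ms: float = 10.0
    seed: int = 0

    def validate_paths(self) -> None:
        required = [self.markers_csv, self.mandible_mesh, self.maxilla_mesh,
                    self.marker_reference_csv, self.landmarks_csv,
                    self.static_frame_csv]
        if self.emg_csv:
            required.append(self.emg_csv)
        missing = [p for p in required if not Path(p).is_file()]
        if missing:
            raise InputError(f"missing input file(s): {missing}")


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ParseError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True),
        encoding="utf-8")
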