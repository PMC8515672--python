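"""The five-step analysis pipeline, end to end.

``run_pipeline`` executes: per-frame mandible pose estimation → static
maxilla registration → landmark trajectories (maxilla frame) → dynamic
occlusion → phase segmentation → EMG burst analysis → reports.  Every
stage logs its parameters; a stage failure aborts with the stage named,
keeping partial outputs on disk.  Given the same config and seed the JSON
reports are byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

from . import __version__
from .core import estimate_pose_series
from .emg import align_to_frames, detect_bursts, preprocess
from .errors import JawtrackError, PipelineError
from .integration import AnatomicalModel, landmark_trajectory, \
    register_maxilla_static
from .io import (
    PipelineConfig,
    burst_report,
    dump_json,
    read_emg,
    read_markers,
    read_mesh,
    read_pointset,
    segmentation_report,
    write_occlusion,
    write_trajectory,
)
from .occlusion import contact_series
from .phases import detect_key_timepoints, phase_statistics
from .plotting import plot_emg_with_trajectory, plot_projections

log = logging.getLogger("jawtrack")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except JawtrackError as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a dict of in-memory stage results."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("jawtrack %s; config: %s", __version__,
             dataclasses.asdict(config))

    capture = _stage("read_markers")(read_markers)(
        config.markers_csv, config.frame_rate)
    model = _stage("load_model")(lambda: AnatomicalModel(
        mandible_mesh=read_mesh(config.mandible_mesh),
        maxilla_mesh=read_mesh(config.maxilla_mesh),
        marker_reference=read_pointset(config.marker_reference_csv),
        landmarks={p: read_pointset(config.landmarks_csv).get(p)
                   for p in read_pointset(config.landmarks_csv).labels},
    ))()
    poses = _stage("pose_estimation")(estimate_pose_series)(
        capture, model.marker_reference)
    static = _stage("static_frame")(read_pointset)(config.static_frame_csv)
    maxilla_pose, static_rmsd = _stage("static_registration")(
        register_maxilla_static)(static, model)
    log.info("static registration RMSD %.6f mm", static_rmsd)

    traj = _stage("trajectory")(landmark_trajectory)(
        poses, maxilla_pose, model, config.landmark)
    write_trajectory(traj, out / f"trajectory_{config.landmark}.csv")
    plot_projections(traj, out / f"trajectory_{config.landmark}.png")

    occl = _stage("occlusion")(contact_series)(
        poses, maxilla_pose, model,
        threshold_mm=config.contact_threshold_mm,
        region=config.occlusion_region)
    write_occlusion(occl, out / "occlusion.csv")
    dump_json({"threshold_mm": occl.threshold_mm,
               "intervals": occl.intervals}, out / "contacts.json")

    seg = _stage("phases")(detect_key_timepoints)(traj, occl)
    stats = phase_statistics(seg)
    dump_json({"segmentation": segmentation_report(seg),
               "statistics": stats}, out / "phases.json")

    results = {
        "capture": capture, "poses": poses, "maxilla_pose": maxilla_pose,
        "static_rmsd": static_rmsd, "trajectory": traj, "occlusion": occl,
        "segmentation": seg, "statistics": stats,
    }

    if config.emg_csv:
        record = _stage("read_emg")(read_emg)(
            config.emg_csv, config.emg_sync_offset_ms)
        env = _stage("emg_preprocess")(preprocess)(
            record, config.emg_highpass_hz, config.emg_envelope_ms)
        bursts = _stage("emg_bursts")(detect_bursts)(
            env, config.emg_baseline_ms, config.emg_k_sd,
            config.emg_min_duration_ms)
        aligned = align_to_frames(bursts, capture.frame_rate,
                                  record.sync_offset_ms)
        dump_json(burst_report(bursts, aligned), out / "emg_bursts.json")
        plot_emg_with_trajectory(traj, record, out / "emg_overview.png")
        results["bursts"] = bursts
        results["aligned_bursts"] = aligned

    dump_json({"version": __version__,
               "config": dataclasses.asdict(config),
               "static_rmsd_mm": static_rmsd,
               "n_frames": capture.n_frames,
               "n_valid_poses": int(poses.valid_mask.sum()),
               "n_cycles": len(seg)}, out / "run_summary.json")
    log.info("pipeline complete: %s", out)
    return results


def simulate_fixture_set(output_dir: str | Path,
                         spec=None,
                         noise_sigma_mm: float = 0.002,
                         mesh_resolution: float = 0.6,
                         seed: int = 0) -> PipelineConfig:
    """Generate a complete synthetic study on disk and its pipeline config.

    Writes marker CSV, dentition meshes (ASCII STL), marker-reference and
    landmark CSVs, the static intercuspal capture frame, phase-locked EMG,
    and the ground-truth JSON.  Returns a ready-to-run
    :class:`PipelineConfig` (also saved as ``config.yaml``).
    """
    from .core import LabeledPointSet
    from .io import save_config, write_emg, write_markers, write_mesh, \
        write_pointset
    from .synthetic import (
        DEFAULT_MARKERS,
        MotionSpec,
        simulate_jaw_motion,
        synth_capture,
        synth_dentition,
        synth_emg,
    )

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = spec if spec is not None else MotionSpec(seed=seed)
    truth = simulate_jaw_motion(spec)
    capture = synth_capture(truth, DEFAULT_MARKERS, noise_sigma_mm,
                            seed=seed + 1)
    mandible, maxilla, landmarks = synth_dentition(resolution=mesh_resolution)
    record = synth_emg(truth, seed=seed + 2)

    write_markers(capture, out / "markers.csv")
    write_mesh(mandible, out / "mandible.stl")
    write_mesh(maxilla, out / "maxilla.stl")
    write_pointset(DEFAULT_MARKERS, out / "marker_reference.csv")
    write_pointset(
        LabeledPointSet(tuple(landmarks),
                        [landmarks[k] for k in landmarks]),
        out / "landmarks.csv")
    # intercuspal static acquisition: mandible at the reference pose
    write_pointset(DEFAULT_MARKERS, out / "static_frame.csv")
    write_emg(record, out / "emg.csv")
    dump_json({
        "spec": dataclasses.asdict(spec),
        "phase_boundaries": truth.phase_boundaries,
        "contact_frames": truth.contact_frames,
        "emg_burst_windows": truth.emg_burst_windows,
        "contact_threshold_mm": truth.contact_threshold_mm,
    }, out / "truth.json")

    config = PipelineConfig(
        markers_csv=str(out / "markers.csv"),
        mandible_mesh=str(out / "mandible.stl"),
        maxilla_mesh=str(out / "maxilla.stl"),
        marker_reference_csv=str(out / "marker_reference.csv"),
        landmarks_csv=str(out / "landmarks.csv"),
        static_frame_csv=str(out / "static_frame.csv"),
        emg_csv=str(out / "emg.csv"),
        output_dir=str(out / "results"),
        frame_rate=spec.frame_rate,
        emg_sync_offset_ms=record.sync_offset_ms,
        seed=seed,
    )
    save_config(config, out / "config.yaml")
    return config
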