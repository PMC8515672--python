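"""Static figure export: trajectory projections, EMG panels, calibration."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .emg import EMGRecord  # noqa: E402
from .evaluation import CalibrationResult  # noqa: E402
from .integration import PLANES, Trajectory, project_plane  # noqa: E402

_PLANE_AXES = {
    "sagittal": ("anterior X (mm)", "superior Z (mm)"),
    "frontal": ("left Y (mm)", "superior Z (mm)"),
    "occlusal": ("anterior X (mm)", "left Y (mm)"),
}


def plot_projections(trajectory: Trajectory, path: str | Path) -> None:
    """Three-panel orthographic projections of one landmark trajectory."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    for ax, plane in zip(axes, PLANES):
        xy = project_plane(trajectory, plane)
        ax.plot(xy[:, 0], xy[:, 1], lw=0.8)
        ax.set_title(plane)
        ax.set_xlabel(_PLANE_AXES[plane][0])
        ax.set_ylabel(_PLANE_AXES[plane][1])
        ax.set_aspect("equal")
    fig.suptitle(f"{trajectory.landmark} trajectory (maxilla frame)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_emg_with_trajectory(trajectory: Trajectory,
                             record: EMGRecord,
                             path: str | Path,
                             cursor_ms: float | None = None) -> None:
    """Sagittal trajectory panel above synchronized EMG channel panels."""
    n_ch = len(record.channels)
    fig, axes = plt.subplots(n_ch + 1, 1, figsize=(10, 2 * (n_ch + 1)),
                             sharex=False)
    ax0 = axes[0]
    xy = project_plane(trajectory, "sagittal")
    ax0.plot(xy[:, 0], xy[:, 1], lw=0.8)
    ax0.set_xlabel("anterior X (mm)")
    ax0.set_ylabel("superior Z (mm)")
    ax0.set_title(f"{trajectory.landmark} (sagittal)")
    cap_t = record.times_ms - record.sync_offset_ms  # capture clock
    for ax, (name, sig) in zip(axes[1:], record.channels.items()):
        ax.plot(cap_t, sig, lw=0.4)
        ax.set_ylabel(f"{name}\n(µV)")
        if cursor_ms is not None:
            ax.axvline(cursor_ms, color="r", lw=0.8)
    axes[-1].set_xlabel("capture time (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_calibration(result: CalibrationResult, path: str | Path) -> None:
    """Percent measurement error against commanded displacement per axis."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for ax, axis in zip(axes, ("x", "y", "z")):
        rows = result.per_axis[axis]
        if len(rows):
            ax.plot(rows[:, 0], rows[:, 2], ".", ms=3)
        ax.set_title(f"{axis}-axis "
                     f"(mean {result.mean_percent_error[axis]:.3f}%)")
        ax.set_xlabel("commanded (mm)")
    axes[0].set_ylabel("error (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
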