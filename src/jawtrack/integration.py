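"""Registering CT anatomy onto capture coordinates and reconstructing
landmark trajectories relative to the maxilla.

The CT frame and the capture frame are linked twice:

1. per motion frame, the mandible pose ``P_t`` (CT -> capture) comes from
   the four mandible markers (:func:`jawtrack.core.estimate_pose_series`);
2. once, at a consolidated intercuspal acquisition with the mandible fixed
   to the cranium, the same marker fit yields the static pose ``P_max``
   that places the maxilla (and the whole cranium) in capture coordinates.

A mandibular landmark ``q`` (CT frame) then moves, relative to the fixed
maxilla, along ``P_max⁻¹ ∘ P_t (q)`` — expressed in a maxilla-fixed frame
axis-aligned with the anatomical CT axes (+X anterior, +Y animal-left,
+Z superior), which makes the sagittal/frontal/occlusal projections
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .core import (
    LabeledPointSet,
    PoseSeries,
    RigidPose,
    fit_rigid,
)
from .errors import InputError

PLANES = {
    "sagittal": (0, 2),   # (X anterior, Z superior)
    "frontal": (1, 2),    # (Y lateral, Z superior)
    "occlusal": (0, 1),   # (X, Y)
}


@dataclass
class AnatomicalModel:
    """Micro-CT derived anatomy: meshes, marker reference, landmarks."""

    mandible_mesh: trimesh.Trimesh
    maxilla_mesh: trimesh.Trimesh
    marker_reference: LabeledPointSet
    landmarks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, mesh in (("mandible", self.mandible_mesh),
                           ("maxilla", self.maxilla_mesh)):
            if mesh is None or len(mesh.faces) == 0:
                raise InputError(f"{name} mesh is empty")
            if not np.all(np.isfinite(mesh.vertices)):
                raise InputError(f"{name} mesh has non-finite vertices")
        pts = self.marker_reference.points
        if len(pts) < 3:
            raise InputError("marker_reference needs >= 3 points")
        if np.linalg.svd(pts - pts.mean(axis=0),
                         compute_uv=False)[1] < 1e-6:
            raise InputError("marker_reference is collinear")
        self.landmarks = {k: np.asarray(v, dtype=float).reshape(3)
                          for k, v in self.landmarks.items()}


@dataclass
class Trajectory:
    """Per-frame positions (mm) of one landmark in the maxilla-fixed frame.

    Invalid (gap) frames are NaN rows.
    """

    landmark: str
    points: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.frame_rate <= 0:
            raise InputError("frame_rate must be positive")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.all(np.isfinite(self.points), axis=1)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(len(self.points)) * 1000.0 / self.frame_rate

    def smoothed(self, window: int = 3) -> "Trajectory":
        """Optional centered moving-average smoothing (gap-preserving)."""
        if window < 1 or window % 2 == 0:
            raise InputError("window must be odd and >= 1")
        out = self.points.copy()
        h = window // 2
        n = len(out)
        for i in range(n):
            seg = self.points[max(0, i - h):min(n, i + h + 1)]
            seg = seg[np.all(np.isfinite(seg), axis=1)]
            if len(seg) and np.all(np.isfinite(self.points[i])):
                out[i] = seg.mean(axis=0)
        return Trajectory(self.landmark, out, self.frame_rate)


def register_maxilla_static(static_capture_frame: LabeledPointSet,
                            model: AnatomicalModel) -> tuple[RigidPose, float]:
    """Fit the CT -> capture pose at the consolidated intercuspal acquisition.

    With mandible and cranium fixed as one rigid unit, this single
    marker-based fit places the maxilla in capture coordinates.  Returns
    the pose and its residual RMSD (mm).
    """
    return fit_rigid(model.marker_reference, static_capture_frame)


def landmark_trajectory(pose_series: PoseSeries,
                        maxilla_pose: RigidPose,
                        model: AnatomicalModel,
                        landmark_name: str) -> Trajectory:
    """Reconstruct one landmark's path in the maxilla-fixed frame.

    Per frame: CT landmark -> capture frame via the mandible pose, then
    -> maxilla-fixed frame via the inverse static maxilla pose.  Invalid
    frames propagate as NaN gaps.
    """
    if landmark_name not in model.landmarks:
        raise InputError(
            f"unknown landmark {landmark_name!r}; "
            f"have {sorted(model.landmarks)}")
    q = model.landmarks[landmark_name]
    inv = maxilla_pose.inverse()
    out = np.full((len(pose_series), 3), np.nan)
    for i, pose in enumerate(pose_series.poses):
        if pose is not None:
            out[i] = inv.apply(pose.apply(q))
    return Trajectory(landmark_name, out, pose_series.frame_rate)


def project_plane(trajectory: Trajectory, plane: str) -> np.ndarray:
    """Orthographic projection onto a named anatomical plane.

    ``sagittal`` -> (X, Z); ``frontal`` -> (Y, Z); ``occlusal`` -> (X, Y).
    Returns an (n, 2) array preserving frame count and NaN gap pattern.
    """
    try:
        i, j = PLANES[plane]
    except KeyError:
        raise InputError(f"plane must be one of {sorted(PLANES)}") from None
    return trajectory.points[:, [i, j]]


def pose_mesh(mesh: trimesh.Trimesh, pose: RigidPose) -> trimesh.Trimesh:
    """Return a copy of ``mesh`` transformed by ``pose`` (for export)."""
    out = mesh.copy()
    out.apply_transform(pose.matrix())
    return out
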