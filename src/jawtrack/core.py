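"""Rigid-body kinematics: poses, least-squares marker fitting, pose series.

The mandible is tracked as a rigid body carrying a set of labeled markers.
Each frame of a capture yields the 6-DOF pose (rotation ``R``, translation
``t``) that best maps the anatomical (CT-frame) marker coordinates onto the
observed capture-frame coordinates in the least-squares sense::

    minimize  sum_i || R m_i + t - y_i ||^2

solved in closed form by centroid alignment plus SVD of the cross-covariance
(the Kabsch solution), with the determinant sign-corrected so the result is
always a proper rotation, never a reflection.

Units are millimetres throughout; frame rates in Hz; angles in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

from .errors import (
    DegenerateGeometryError,
    InputError,
    InsufficientCorrespondenceError,
)

#: orthonormality / round-trip tolerance
POSE_ATOL = 1e-9
#: smallest admissible singular value (mm) of the centered marker configuration
DEGENERACY_SVAL_MM = 1e-6


@dataclass(frozen=True)
class RigidPose:
    """A proper rigid transform ``p -> rotation @ p + translation``.

    Parameters
    ----------
    rotation
        3x3 orthonormal matrix with determinant +1.
    translation
        3-vector in mm.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(R)) and np.all(np.isfinite(t))):
            raise InputError("pose contains non-finite values")
        if np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise InputError("rotation is not orthonormal")
        if np.linalg.det(R) < 0:
            raise InputError("rotation is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) or (3,) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Return ``self ∘ other`` (apply ``other`` first, then ``self``)."""
        return RigidPose(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidPose":
        Rt = self.rotation.T
        return RigidPose(Rt, -Rt @ self.translation)

    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def is_identity(self, atol: float = POSE_ATOL) -> bool:
        return bool(
            np.allclose(self.rotation, np.eye(3), atol=atol)
            and np.allclose(self.translation, 0.0, atol=atol)
        )


@dataclass
class LabeledPointSet:
    """Ordered labeled 3D points (mm), e.g. one capture frame of markers."""

    labels: tuple[str, ...]
    points: np.ndarray
    frame_id: int | None = None

    def __post_init__(self) -> None:
        self.labels = tuple(str(l) for l in self.labels)
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.labels) != len(self.points):
            raise InputError(
                f"{len(self.labels)} labels but {len(self.points)} points"
            )
        if len(self.labels) == 0:
            raise InputError("empty point set")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("duplicate marker labels")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, label: str) -> np.ndarray:
        return self.points[self.labels.index(label)]

    def subset(self, labels: Sequence[str]) -> "LabeledPointSet":
        idx = [self.labels.index(l) for l in labels]
        return LabeledPointSet(tuple(labels), self.points[idx], self.frame_id)

    def finite_subset(self) -> "LabeledPointSet | None":
        """Drop labels with non-finite coordinates; None if nothing is left."""
        ok = np.all(np.isfinite(self.points), axis=1)
        if not ok.any():
            return None
        labs = tuple(l for l, k in zip(self.labels, ok) if k)
        return LabeledPointSet(labs, self.points[ok], self.frame_id)


@dataclass
class CaptureSequence:
    """An ordered sequence of marker frames at a fixed frame rate."""

    frames: list[LabeledPointSet]
    frame_rate: float

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise InputError("frame_rate must be positive")
        if not self.frames:
            raise InputError("empty capture")
        labels = self.frames[0].labels
        for f in self.frames:
            if f.labels != labels:
                raise InputError("all frames must share one label set")
        ids = [f.frame_id for f in self.frames]
        if all(i is not None for i in ids) and any(
            b <= a for a, b in zip(ids, ids[1:])
        ):
            raise InputError("frame_ids must be strictly increasing")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.frames[0].labels

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * 1000.0 / self.frame_rate

    def as_array(self) -> np.ndarray:
        """(n_frames, n_markers, 3) array in frame order."""
        return np.stack([f.points for f in self.frames])


@dataclass
class PoseSeries:
    """Per-frame rigid poses with fit residuals; invalid frames carry None."""

    poses: list[RigidPose | None]
    frame_rate: float
    residual_rmsd: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.residual_rmsd is None:
            self.residual_rmsd = np.full(len(self.poses), np.nan)
        self.residual_rmsd = np.asarray(self.residual_rmsd, dtype=float)
        if len(self.residual_rmsd) != len(self.poses):
            raise InputError("residual_rmsd length mismatch")

    def __len__(self) -> int:
        return len(self.poses)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.array([p is not None for p in self.poses])

    def interpolate_gaps(self) -> "PoseSeries":
        """Fill invalid frames: linear on translation, slerp on rotation.

        Gaps at the ends are filled by nearest valid pose (constant
        extrapolation).  Residuals of filled frames stay NaN.
        """
        valid = np.flatnonzero(self.valid_mask)
        if valid.size == 0:
            raise InputError("cannot interpolate: no valid poses")
        if valid.size == len(self.poses):
            return PoseSeries(list(self.poses), self.frame_rate,
                              self.residual_rmsd.copy())
        rots = Rotation.from_matrix(
            np.stack([self.poses[i].rotation for i in valid])
        )
        trans = np.stack([self.poses[i].translation for i in valid])
        out: list[RigidPose | None] = []
        n = len(self.poses)
        if valid.size == 1:
            only = self.poses[valid[0]]
            out = [only] * n
        else:
            slerp = Slerp(valid.astype(float), rots)
            for i in range(n):
                if self.poses[i] is not None:
                    out.append(self.poses[i])
                    continue
                j = float(np.clip(i, valid[0], valid[-1]))
                R = slerp([j]).as_matrix()[0]
                t = np.array([
                    np.interp(j, valid.astype(float), trans[:, k])
                    for k in range(3)
                ])
                out.append(RigidPose(R, t))
        return PoseSeries(out, self.frame_rate, self.residual_rmsd.copy())


def _common(reference: LabeledPointSet,
            observed: LabeledPointSet) -> tuple[np.ndarray, np.ndarray]:
    labels = [l for l in reference.labels if l in observed.labels]
    if len(labels) < 3:
        raise InsufficientCorrespondenceError(
            f"only {len(labels)} common labels; need >= 3"
        )
    ref = reference.subset(labels).points
    obs = observed.subset(labels).points
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(obs))):
        raise InputError("non-finite marker coordinates")
    return ref, obs


def fit_rigid(reference: LabeledPointSet,
              observed: LabeledPointSet) -> tuple[RigidPose, float]:
    """Least-squares rigid fit mapping ``reference`` onto ``observed``.

    Returns the pose minimizing ``sum_i ||R r_i + t - o_i||^2`` over proper
    rotations, and the residual RMSD (mm).  Matching is by label; at least
    three non-collinear common markers are required.

    Raises
    ------
    InsufficientCorrespondenceError
        Fewer than 3 common labels.
    DegenerateGeometryError
        Common reference markers (near-)collinear: the rotation about the
        marker axis is unobservable and a reflection could masquerade as a
        rotation, so no pose is returned.
    """
    ref, obs = _common(reference, observed)
    ref_c = ref.mean(axis=0)
    obs_c = obs.mean(axis=0)
    A = ref - ref_c
    B = obs - obs_c
    # rank of the centered reference configuration decides identifiability:
    # rank >= 2 (planar is fine) is needed for a unique proper rotation
    svals = np.linalg.svd(A, compute_uv=False)
    if svals[1] < DEGENERACY_SVAL_MM:
        raise DegenerateGeometryError(
            "marker configuration is collinear within tolerance"
        )
    H = A.T @ B  # cross-covariance
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d == 0:
        d = 1.0
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = obs_c - R @ ref_c
    pose = RigidPose(R, t)
    rmsd = float(np.sqrt(np.mean(np.sum((pose.apply(ref) - obs) ** 2, axis=1))))
    return pose, rmsd


def apply_pose(pose: RigidPose, points: LabeledPointSet) -> LabeledPointSet:
    """Map every point of a labeled set through a pose; labels preserved."""
    if not np.all(np.isfinite(points.points)):
        raise InputError("non-finite coordinates")
    return LabeledPointSet(points.labels, pose.apply(points.points),
                           points.frame_id)


def compose_invert(a: RigidPose, b: RigidPose | None = None) -> RigidPose:
    """``a ∘ b`` when ``b`` is given (apply ``b`` first), else ``a⁻¹``."""
    return a.inverse() if b is None else a.compose(b)


def estimate_pose_series(capture: CaptureSequence,
                         reference: LabeledPointSet,
                         *,
                         interpolate: bool = False) -> PoseSeries:
    """Fit one rigid pose per capture frame against the reference markers.

    Frames with missing (non-finite) markers are fit on the remaining
    markers when at least three usable correspondences survive; otherwise
    the frame is flagged invalid (pose ``None``) and carried as a gap unless
    ``interpolate`` is set.

    Raises
    ------
    InputError
        If every frame is invalid.
    """
    missing = [l for l in reference.labels if l not in capture.labels]
    if missing:
        raise InputError(f"reference labels not in capture: {missing}")
    poses: list[RigidPose | None] = []
    rmsds = np.full(capture.n_frames, np.nan)
    for i, frame in enumerate(capture.frames):
        usable = frame.finite_subset()
        if usable is None:
            poses.append(None)
            continue
        try:
            pose, rmsd = fit_rigid(reference, usable)
        except (InsufficientCorrespondenceError, DegenerateGeometryError):
            poses.append(None)
            continue
        poses.append(pose)
        rmsds[i] = rmsd
    series = PoseSeries(poses, capture.frame_rate, rmsds)
    if not series.valid_mask.any():
        raise InputError("no frame had >= 3 usable markers")
    if interpolate:
        series = series.interpolate_gaps()
    return series
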