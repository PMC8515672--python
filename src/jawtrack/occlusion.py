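"""Dynamic occlusion: per-frame clearance between the posed mandible mesh
and the static maxilla mesh, and detection of contact intervals.

Clearance uses the symmetric vertex-to-surface metric: the minimum over
(a) posed-mandible vertices against maxilla triangles and (b) maxilla
vertices against posed-mandible triangles.  Exact point-triangle distances
are evaluated only for candidate triangles surviving a KD-tree pruning
stage (nearest-vertex upper bounds, centroid-ball lower bounds), so the
result equals the exhaustive scan while scaling to meshes with many
thousands of faces.  Interpenetrating meshes report clearance 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from trimesh.triangles import closest_point as _tri_closest

from .core import PoseSeries, RigidPose
from .errors import InputError
from .integration import AnatomicalModel

_REGION_LANDMARKS = {"molar": ("molar",), "incisor": ("incisor",)}


class _MeshDistance:
    """Exact point-set-to-mesh minimum distance with KD-tree pruning."""

    def __init__(self, mesh: trimesh.Trimesh):
        if len(mesh.faces) == 0:
            raise InputError("empty mesh")
        self.vertices = np.asarray(mesh.vertices, dtype=float)
        self.triangles = self.vertices[np.asarray(mesh.faces)]
        self.centroids = self.triangles.mean(axis=1)
        self.radii = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2).max(axis=1)
        self.r_max = float(self.radii.max())
        self._ctree = cKDTree(self.centroids)
        self._vtree = cKDTree(self.vertices)

    def min_distance(self, points: np.ndarray
                     ) -> tuple[float, np.ndarray, np.ndarray]:
        """Global min distance from ``points`` to the mesh surface.

        Exact: the nearest-vertex distance gives a global upper bound
        ``b``; any (point, triangle) pair beating it must have a centroid
        within ``b + r_max`` of the point, and all such pairs are
        evaluated with exact point-triangle distances.

        Returns (distance, query point, surface point).
        """
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        d_ub, v_idx = self._vtree.query(points)
        i0 = int(np.argmin(d_ub))
        best = float(d_ub[i0])
        best_q = points[i0]
        best_s = self.vertices[v_idx[i0]]
        # prune points that provably cannot beat the bound
        d_c1, _ = self._ctree.query(points)
        live = np.flatnonzero(d_c1 - self.r_max < best)
        if live.size == 0 or best == 0.0:
            return best, best_q, best_s
        balls = self._ctree.query_ball_point(points[live],
                                             best + self.r_max)
        pt_idx = np.repeat(live, [len(b) for b in balls])
        tri_idx = np.fromiter((t for b in balls for t in b), dtype=np.intp,
                              count=len(pt_idx))
        for lo in range(0, len(pt_idx), 1_000_000):
            sl = slice(lo, lo + 1_000_000)
            q = points[pt_idx[sl]]
            closest = _tri_closest(self.triangles[tri_idx[sl]], q)
            dists = np.linalg.norm(closest - q, axis=1)
            j = int(np.argmin(dists)) if len(dists) else 0
            if len(dists) and dists[j] < best:
                best = float(dists[j])
                best_q = q[j]
                best_s = closest[j]
        return best, best_q, best_s


def _region_face_mask(mesh: trimesh.Trimesh, region: str,
                      landmarks: dict[str, np.ndarray] | None,
                      radius_mm: float) -> np.ndarray:
    if region == "all":
        return np.ones(len(mesh.faces), dtype=bool)
    if region not in _REGION_LANDMARKS:
        raise InputError("region must be 'all', 'molar' or 'incisor'")
    if not landmarks:
        raise InputError(f"region {region!r} needs landmark coordinates")
    keys = [k for k in landmarks
            if any(s in k for s in _REGION_LANDMARKS[region])]
    if not keys:
        raise InputError(f"no landmark matches region {region!r}")
    centers = np.stack([landmarks[k] for k in keys])
    # mirror across the midsagittal plane so both molar rows are covered
    centers = np.vstack([centers, centers * np.array([1.0, -1.0, 1.0])])
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    d = np.linalg.norm(centroids[:, None, :] - centers[None], axis=2)
    mask = (d <= radius_mm).any(axis=1)
    if not mask.any():
        raise InputError(f"region {region!r} mask is empty at "
                         f"radius {radius_mm} mm")
    return mask


def _submesh(mesh: trimesh.Trimesh, mask: np.ndarray) -> trimesh.Trimesh:
    if mask.all():
        return mesh
    return trimesh.Trimesh(vertices=mesh.vertices,
                           faces=np.asarray(mesh.faces)[mask],
                           process=False)


def _intersects(points: np.ndarray, mesh: trimesh.Trimesh,
                candidates: int = 8) -> bool:
    """Containment test of the query points nearest to ``mesh``.

    A full point-in-mesh scan per frame is prohibitive; penetration in a
    dentition scene happens at the closest features, so testing the few
    nearest vertices is sufficient in practice (documented limitation).
    """
    tree = cKDTree(np.asarray(mesh.vertices))
    d, _ = tree.query(points)
    sel = points[np.argsort(d)[:candidates]]
    try:
        return bool(np.any(mesh.contains(sel)))
    except Exception:
        return False


def min_clearance(mandible_mesh: trimesh.Trimesh,
                  maxilla_mesh: trimesh.Trimesh,
                  pose: RigidPose | None = None,
                  region: str = "all",
                  landmarks: dict[str, np.ndarray] | None = None,
                  region_radius_mm: float = 1.5,
                  check_intersection: bool = True,
                  ) -> tuple[float, np.ndarray, np.ndarray]:
    """Minimum clearance (mm) between the posed mandible and the maxilla.

    Parameters
    ----------
    pose
        Rigid pose applied to the mandible (identity if None).
    region
        ``all``, ``molar`` or ``incisor``; restricts mandible faces to
        those within ``region_radius_mm`` of the matching landmark(s),
        given in the (unposed) mandible frame.
    check_intersection
        Test the closest vertices for containment and return 0 when the
        meshes interpenetrate.

    Returns
    -------
    clearance, point_on_mandible, point_on_maxilla
        Points in maxilla coordinates; clearance 0 when touching or
        intersecting.
    """
    mask = _region_face_mask(mandible_mesh, region, landmarks,
                             region_radius_mm)
    mand = _submesh(mandible_mesh, mask)
    if pose is not None and not pose.is_identity(atol=0.0):
        mand = mand.copy()
        mand.apply_transform(pose.matrix())
    dist_max = _MeshDistance(maxilla_mesh)
    dist_man = _MeshDistance(mand)
    d1, q1, s1 = dist_max.min_distance(mand.vertices)
    d2, q2, s2 = dist_man.min_distance(np.asarray(maxilla_mesh.vertices))
    if d1 <= d2:
        d, p_man, p_max = d1, q1, s1
    else:
        d, p_man, p_max = d2, s2, q2
    if check_intersection and d > 0:
        if _intersects(np.asarray(mand.vertices), maxilla_mesh) or \
           _intersects(np.asarray(maxilla_mesh.vertices), mand):
            d = 0.0
    return float(d), p_man, p_max


@dataclass
class OcclusionSeries:
    """Per-frame minimum clearance and contact flags."""

    clearance_mm: np.ndarray
    threshold_mm: float
    frame_rate: float

    def __post_init__(self) -> None:
        self.clearance_mm = np.asarray(self.clearance_mm, dtype=float)
        if self.threshold_mm < 0:
            raise InputError("threshold must be >= 0")

    @property
    def contact(self) -> np.ndarray:
        """Contact flag per frame (False at gap frames)."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.clearance_mm,
                                 nan=np.inf) <= self.threshold_mm

    @property
    def intervals(self) -> list[tuple[int, int]]:
        """Maximal contact runs as (first, last) inclusive frame pairs."""
        flags = self.contact
        runs, start = [], None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            elif not f and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(flags) - 1))
        return runs

    def __len__(self) -> int:
        return len(self.clearance_mm)


def contact_series(pose_series: PoseSeries,
                   maxilla_pose: RigidPose,
                   model: AnatomicalModel,
                   threshold_mm: float = 0.05,
                   region: str = "all",
                   region_radius_mm: float = 1.5) -> OcclusionSeries:
    """Clearance and contact flags over a pose series, in the maxilla frame.

    Per frame the mandible is placed relative to the static maxilla by
    ``maxilla_pose⁻¹ ∘ P_t``; invalid frames propagate as NaN clearance.
    """
    if threshold_mm <= 0:
        raise InputError("threshold_mm must be > 0")
    inv = maxilla_pose.inverse()
    mask = _region_face_mask(model.mandible_mesh, region, model.landmarks,
                             region_radius_mm)
    mand = _submesh(model.mandible_mesh, mask)
    mand_verts = np.asarray(mand.vertices, dtype=float)
    dist_max = _MeshDistance(model.maxilla_mesh)
    dist_man = _MeshDistance(mand)  # mandible-frame tree, reused every frame
    maxi_verts = np.asarray(model.maxilla_mesh.vertices, dtype=float)
    out = np.full(len(pose_series), np.nan)
    for i, p in enumerate(pose_series.poses):
        if p is None:
            continue
        rel = inv.compose(p)  # mandible CT -> maxilla frame
        d1, q1, _ = dist_max.min_distance(rel.apply(mand_verts))
        # map maxilla vertices into the mandible frame: same distances,
        # but the static mandible KD-trees can be reused
        d2, _, _ = dist_man.min_distance(rel.inverse().apply(maxi_verts))
        d = min(d1, d2)
        if d > 0 and d <= max(2 * threshold_mm, 0.2):
            # near-contact frames: check for interpenetration
            posed = rel.apply(mand_verts)
            if _intersects(posed, model.maxilla_mesh):
                d = 0.0
        out[i] = d
    return OcclusionSeries(out, threshold_mm, pose_series.frame_rate)
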