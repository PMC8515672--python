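"""Rigid-pose mathematics: fitting, transforms, pose-series estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import jawtrack as jt
from jawtrack.errors import (
    DegenerateGeometryError,
    InputError,
    InsufficientCorrespondenceError,
)

from conftest import random_pose

REF = jt.DEFAULT_MARKERS


def _apply(labels, R, t, pts):
    return jt.LabeledPointSet(labels, pts @ R.T + t)


class TestFitRigid:
    def test_identical_sets_give_identity(self):
        pose, rmsd = jt.fit_rigid(REF, REF)
        assert pose.is_identity()
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_forced_rotation_and_shift_recovered_exactly(self):
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        t = np.array([1.0, 2.0, 3.0])
        pose, rmsd = jt.fit_rigid(REF, _apply(REF.labels, R, t, REF.points))
        assert np.abs(pose.rotation - R).max() < 1e-9
        assert np.abs(pose.translation - t).max() < 1e-9
        assert rmsd < 1e-9

    @pytest.mark.parametrize("seed", range(5))
    def test_random_noiseless_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        truth = random_pose(rng)
        obs = jt.apply_pose(truth, REF)
        pose, rmsd = jt.fit_rigid(REF, obs)
        assert np.abs(pose.rotation - truth.rotation).max() < 1e-9
        assert np.abs(pose.translation - truth.translation).max() < 1e-9
        assert rmsd < 1e-9

    def test_matches_brute_force_rotation_search(self):
        """The SVD fit attains the global least-squares optimum found by a
        grid + local search over the 3-parameter rotation space."""
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(4, 3))
        labels = tuple("abcd")
        ref = jt.LabeledPointSet(labels, pts)
        truth = random_pose(rng)
        obs_pts = truth.apply(pts) + rng.normal(0, 0.01, (4, 3))
        obs = jt.LabeledPointSet(labels, obs_pts)
        pose, rmsd = jt.fit_rigid(ref, obs)

        A = pts - pts.mean(axis=0)
        B = obs_pts - obs_pts.mean(axis=0)

        def objective(rotvec):
            R = Rotation.from_rotvec(rotvec).as_matrix()
            return np.sum((A @ R.T - B) ** 2)

        best = None
        grid = np.linspace(-np.pi, np.pi, 7)
        for rx in grid:
            for ry in grid:
                for rz in grid:
                    res = minimize(objective, [rx, ry, rz],
                                   method="Nelder-Mead",
                                   options={"xatol": 1e-10, "fatol": 1e-14})
                    if best is None or res.fun < best.fun:
                        best = res
        R_oracle = Rotation.from_rotvec(best.x).as_matrix()
        assert np.sum((A @ pose.rotation.T - B) ** 2) == pytest.approx(
            best.fun, rel=1e-6)
        assert np.abs(pose.rotation - R_oracle).max() < 1e-4

    def test_matches_scipy_align_vectors(self):
        """Cross-check against an independent Kabsch implementation."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            pts = rng.normal(size=(5, 3))
            obs = random_pose(rng).apply(pts) + rng.normal(0, 0.05, (5, 3))
            labels = tuple("abcde")
            pose, _ = jt.fit_rigid(jt.LabeledPointSet(labels, pts),
                                   jt.LabeledPointSet(labels, obs))
            A = pts - pts.mean(axis=0)
            B = obs - obs.mean(axis=0)
            R_ref, _ = Rotation.align_vectors(B, A)
            assert np.abs(pose.rotation - R_ref.as_matrix()).max() < 1e-8

    def test_never_returns_reflection(self):
        rng = np.random.default_rng(3)
        # near-planar noisy configurations tempt the raw SVD into det = -1
        for _ in range(200):
            pts = rng.normal(size=(4, 3)) * np.array([1.0, 1.0, 1e-4])
            obs = pts[:, [0, 1, 2]].copy()
            obs[:, 2] *= -1.0  # reflected observation
            obs += rng.normal(0, 0.05, (4, 3))
            labels = tuple("abcd")
            pose, _ = jt.fit_rigid(jt.LabeledPointSet(labels, pts),
                                   jt.LabeledPointSet(labels, obs))
            assert np.linalg.det(pose.rotation) == pytest.approx(1.0,
                                                                 abs=1e-9)

    def test_too_few_common_labels_raises(self):
        a = jt.LabeledPointSet(("a", "b", "c"), np.eye(3))
        b = jt.LabeledPointSet(("a", "b", "x"), np.eye(3))
        with pytest.raises(InsufficientCorrespondenceError):
            jt.fit_rigid(a, b)

    def test_collinear_reference_raises(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                       dtype=float)
        ps = jt.LabeledPointSet(tuple("abcd"), pts)
        with pytest.raises(DegenerateGeometryError):
            jt.fit_rigid(ps, ps)


class TestApplyCompose:
    def test_identity_returns_input(self):
        out = jt.apply_pose(jt.RigidPose.identity(), REF)
        assert np.array_equal(out.points, REF.points)
        assert out.labels == REF.labels

    def test_pure_translation(self):
        pose = jt.RigidPose(np.eye(3), [0.0, 0.0, 1.0])
        out = pose.apply(np.zeros(3))
        assert np.allclose(out, [0, 0, 1])

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000))
    def test_rigidity_preserves_pairwise_distances(self, seed):
        rng = np.random.default_rng(seed)
        pose = random_pose(rng)
        pts = rng.normal(size=(6, 3)) * 5
        out = pose.apply(pts)
        d_in = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        d_out = np.linalg.norm(out[:, None] - out[None], axis=2)
        assert np.abs(d_in - d_out).max() < 1e-9

    def test_compose_with_inverse_is_identity(self):
        rng = np.random.default_rng(0)
        a = random_pose(rng)
        assert jt.compose_invert(a, jt.compose_invert(a)).is_identity()

    def test_identity_compose_is_neutral(self):
        b = random_pose(np.random.default_rng(1))
        c = jt.compose_invert(jt.RigidPose.identity(), b)
        assert np.allclose(c.rotation, b.rotation, atol=1e-12)
        assert np.allclose(c.translation, b.translation, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_composition_matches_sequential_application(self, seed):
        rng = np.random.default_rng(seed)
        a, b = random_pose(rng), random_pose(rng)
        p = rng.normal(size=(10, 3))
        assert np.allclose(jt.compose_invert(a, b).apply(p),
                           a.apply(b.apply(p)), atol=1e-9)

    def test_reflection_rejected_on_construction(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(InputError):
            jt.RigidPose(R, np.zeros(3))


class TestPoseSeries:
    def _capture(self, poses, noise=0.0, rng=None):
        frames = []
        for i, p in enumerate(poses):
            pts = p.apply(REF.points)
            if noise and rng is not None:
                pts = pts + rng.normal(0, noise, pts.shape)
            frames.append(jt.LabeledPointSet(REF.labels, pts, frame_id=i))
        return jt.CaptureSequence(frames, 200.0)

    def test_static_capture_gives_identity_every_frame(self):
        cap = self._capture([jt.RigidPose.identity()] * 8)
        series = jt.estimate_pose_series(cap, REF)
        assert all(p.is_identity() for p in series.poses)

    def test_known_pose_sequence_recovered_noiselessly(self):
        rng = np.random.default_rng(5)
        truth = [random_pose(rng) for _ in range(20)]
        series = jt.estimate_pose_series(self._capture(truth), REF)
        for est, exp in zip(series.poses, truth):
            assert np.abs(est.rotation - exp.rotation).max() < 1e-9
            assert np.abs(est.translation - exp.translation).max() < 1e-9

    def test_noise_error_consistent_with_monte_carlo_prediction(self):
        """With the reference centered at its centroid, the translation
        estimate is the observed centroid, so per-axis error is
        N(0, sigma^2/4) for four markers; the mean error norm over 1000
        replicates must match the chi(3) expectation."""
        sigma = 0.005
        labels = REF.labels
        centered = jt.LabeledPointSet(labels,
                                      REF.points - REF.points.mean(axis=0))
        rng = np.random.default_rng(42)
        cap = self._capture([jt.RigidPose.identity()] * 1000, 0.0)
        frames = [jt.LabeledPointSet(labels,
                                     centered.points
                                     + rng.normal(0, sigma, (4, 3)),
                                     frame_id=i) for i in range(1000)]
        cap = jt.CaptureSequence(frames, 200.0)
        series = jt.estimate_pose_series(cap, centered)
        errs = np.array([np.linalg.norm(p.translation)
                         for p in series.poses])
        # E||N(0, (sigma/2)^2 I_3)|| = (sigma/2) * sqrt(2) * Gamma(2)/Gamma(1.5)
        expected = (sigma / 2.0) * np.sqrt(2) * 1.0 / (np.sqrt(np.pi) / 2)
        se = errs.std(ddof=1) / np.sqrt(len(errs))
        assert abs(errs.mean() - expected) < 5 * se

    def test_missing_marker_uses_remaining_three(self):
        rng = np.random.default_rng(9)
        truth = [random_pose(rng) for _ in range(5)]
        cap = self._capture(truth)
        cap.frames[2].points[3] = np.nan
        series = jt.estimate_pose_series(cap, REF)
        assert series.valid_mask.all()
        assert np.abs(series.poses[2].rotation
                      - truth[2].rotation).max() < 1e-9

    def test_frame_with_two_markers_flagged_not_fatal(self):
        cap = self._capture([jt.RigidPose.identity()] * 4)
        cap.frames[1].points[2:] = np.nan
        series = jt.estimate_pose_series(cap, REF)
        assert not series.valid_mask[1]
        assert series.valid_mask[[0, 2, 3]].all()

    def test_all_frames_invalid_is_fatal(self):
        cap = self._capture([jt.RigidPose.identity()] * 3)
        for f in cap.frames:
            f.points[:] = np.nan
        with pytest.raises(InputError):
            jt.estimate_pose_series(cap, REF)

    def test_gap_interpolation_fills_between_neighbors(self):
        t0 = jt.RigidPose(np.eye(3), [0.0, 0.0, 0.0])
        t2 = jt.RigidPose(np.eye(3), [2.0, 0.0, 0.0])
        cap = self._capture([t0, t0, t2])
        cap.frames[1].points[:] = np.nan
        series = jt.estimate_pose_series(cap, REF, interpolate=True)
        assert series.valid_mask.all() or series.poses[1] is not None
        assert np.allclose(series.poses[1].translation, [1.0, 0.0, 0.0],
                           atol=1e-9)

    def test_unknown_reference_label_rejected(self):
        cap = self._capture([jt.RigidPose.identity()] * 2)
        ref = jt.LabeledPointSet(("m1", "m2", "zz"), REF.points[:3])
        with pytest.raises(InputError):
            jt.estimate_pose_series(cap, ref)
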