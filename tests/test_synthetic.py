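"""Synthetic generator: motion truth, captures, dentition, EMG."""

import numpy as np
import pytest

import jawtrack as jt
from jawtrack.errors import DegenerateGeometryError
from jawtrack.synthetic import EMG_CHANNELS, FOSSA_DEPTH


class TestMotion:
    def test_zero_amplitudes_give_constant_identity(self):
        spec = jt.MotionSpec(gape_mm=0.0, ap_excursion_mm=0.0,
                             lateral_mm=0.0, n_cycles=2)
        truth = jt.simulate_jaw_motion(spec)
        assert truth.phase_boundaries == []
        for p in truth.pose_series.poses:
            assert p.is_identity(atol=1e-12)

    def test_thirty_frames_per_cycle_at_200hz(self):
        # 150-ms cycles at 200 frames/s: 30 points per cycle, 5 ms apart
        spec = jt.MotionSpec(n_cycles=1, cycle_ms=150.0, frame_rate=200.0)
        assert spec.frames_per_cycle == 30
        truth = jt.simulate_jaw_motion(spec)
        assert len(truth.pose_series) == 31  # one cycle plus its closure
        assert np.isclose(1000.0 / spec.frame_rate, 5.0)

    def test_recorded_boundaries_equal_extrema_rescan(self, default_truth):
        """Independent extrema scan of the generated molar path."""
        mol = default_truth.molar_path
        fpc = default_truth.spec.frames_per_cycle
        for k, b in enumerate(default_truth.phase_boundaries):
            s, e = int(round(k * fpc)), int(round((k + 1) * fpc))
            z = mol[s:e + 1, 2]
            x = mol[s:e + 1, 0]
            assert b["max_closing"] == s + int(np.argmax(z[:-1]))
            assert b["most_anterior"] == s + int(np.argmax(x))
            assert b["max_opening"] == s + int(np.argmin(z))
            mo = b["max_opening"] - s
            assert b["most_posterior"] == s + mo + int(np.argmin(x[mo:]))

    def test_key_timepoints_in_cyclic_order(self, default_truth):
        for b in default_truth.phase_boundaries:
            assert (b["max_closing"] < b["most_anterior"]
                    < b["max_opening"] < b["most_posterior"])

    def test_exactly_one_extremum_pair_per_cycle(self, default_truth):
        mol = default_truth.molar_path
        for k in range(default_truth.spec.n_cycles):
            s, e = 30 * k, 30 * (k + 1)
            # X: interior max then interior min -> two reversals;
            # Z: max sits on the cycle boundary, interior min -> one
            for axis, expected in ((0, 2), (2, 1)):
                d = np.sign(np.diff(mol[s:e + 1, axis]))
                d = d[d != 0]
                reversals = int(np.sum(d[1:] * d[:-1] < 0))
                assert reversals == expected

    def test_condylar_asymmetry(self, default_truth):
        """Working condyle reverses mid-opening; balancing condyle keeps
        advancing to the end of the opening phase."""
        b = default_truth.phase_boundaries[0]
        cw = default_truth.landmark_paths["condyle_right"][:31, 0]
        cb = default_truth.landmark_paths["condyle_left"][:31, 0]
        mid = (b["max_closing"] + b["max_opening"]) / 2
        assert abs(int(np.argmax(cw)) - mid) <= 2
        assert abs(int(np.argmax(cb)) - b["max_opening"]) <= 2

    def test_condyles_translate_nearly_parallel_to_occlusal_plane(
            self, default_truth):
        """The hinge-dominant pitch keeps condylar vertical motion well
        below the antero-posterior excursion."""
        for name in ("condyle_left", "condyle_right"):
            path = default_truth.landmark_paths[name]
            assert np.ptp(path[:, 2]) < 0.3 * np.ptp(path[:, 0])

    def test_working_side_mirror(self):
        truth = jt.simulate_jaw_motion(jt.MotionSpec(working_side="left",
                                                     n_cycles=2))
        cw = truth.landmark_paths["condyle_left"][:31, 0]
        cb = truth.landmark_paths["condyle_right"][:31, 0]
        assert int(np.argmax(cw)) < int(np.argmax(cb))

    def test_contact_onset_coincides_with_most_posterior(self, default_truth):
        fpc = default_truth.spec.frames_per_cycle
        onsets = [a for a, _ in default_truth.contact_frames if a > 0]
        for k, b in enumerate(default_truth.phase_boundaries):
            in_cycle = [a for a in onsets
                        if b["max_opening"] <= a <= (k + 1) * fpc]
            assert in_cycle, f"no contact onset in cycle {k}"
            assert abs(in_cycle[0] - b["most_posterior"]) <= 2

    def test_truth_contact_matches_analytic_clearance(self, default_truth):
        flags = default_truth.clearance_mm <= \
            default_truth.contact_threshold_mm
        runs = []
        start = None
        for i, f in enumerate(flags):
            if f and start is None:
                start = i
            elif not f and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(flags) - 1))
        assert runs == default_truth.contact_frames

    def test_determinism(self):
        a = jt.simulate_jaw_motion(jt.MotionSpec(n_cycles=2))
        b = jt.simulate_jaw_motion(jt.MotionSpec(n_cycles=2))
        assert np.array_equal(a.molar_path, b.molar_path)
        assert a.phase_boundaries == b.phase_boundaries


class TestCapture:
    def test_noiseless_round_trip(self, short_truth):
        cap = jt.synth_capture(short_truth, noise_sigma_mm=0.0)
        series = jt.estimate_pose_series(cap, jt.DEFAULT_MARKERS)
        for est, exp in zip(series.poses, short_truth.pose_series.poses):
            assert np.abs(est.rotation - exp.rotation).max() < 1e-9
            assert np.abs(est.translation - exp.translation).max() < 1e-9

    def test_same_seed_identical(self, short_truth):
        a = jt.synth_capture(short_truth, noise_sigma_mm=0.01, seed=5)
        b = jt.synth_capture(short_truth, noise_sigma_mm=0.01, seed=5)
        assert np.array_equal(a.as_array(), b.as_array())

    def test_collinear_marker_geometry_rejected(self, short_truth):
        geom = jt.LabeledPointSet(("a", "b", "c"),
                                  [[0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            jt.synth_capture(short_truth, geom)

    def test_fit_rmsd_consistent_with_noise_model(self):
        """For n markers with isotropic noise sigma, the residual sum of
        squares of the rigid fit is sigma^2 * chi^2 with 3n-6 degrees of
        freedom, so E[RMSD^2] = sigma^2 (3n-6)/n."""
        sigma = 0.01
        truth = jt.simulate_jaw_motion(jt.MotionSpec(n_cycles=1))
        frames = []
        rng = np.random.default_rng(17)
        pose0 = truth.pose_series.poses[0]
        for i in range(1000):
            pts = pose0.apply(jt.DEFAULT_MARKERS.points)
            pts = pts + rng.normal(0, sigma, pts.shape)
            frames.append(jt.LabeledPointSet(jt.DEFAULT_MARKERS.labels, pts,
                                             frame_id=i))
        series = jt.estimate_pose_series(
            jt.CaptureSequence(frames, 200.0), jt.DEFAULT_MARKERS)
        msd = series.residual_rmsd ** 2
        expected = sigma ** 2 * (3 * 4 - 6) / 4
        se = msd.std(ddof=1) / np.sqrt(len(msd))
        assert abs(msd.mean() - expected) < 5 * se


class TestDentition:
    def test_intercuspal_clearance_zero(self, dentition):
        mandible, maxilla, _ = dentition
        d, _, _ = jt.min_clearance(mandible, maxilla)
        assert d == pytest.approx(0.0, abs=0.05)

    def test_lowered_mandible_clearance_one_mm(self, dentition):
        mandible, maxilla, _ = dentition
        pose = jt.RigidPose(np.eye(3), [0.0, 0.0, -1.0])
        d, _, _ = jt.min_clearance(mandible, maxilla, pose=pose)
        assert d == pytest.approx(1.0, abs=0.05)

    def test_four_named_landmarks(self, dentition):
        _, _, landmarks = dentition
        assert set(landmarks) == {"incisor_edge", "molar_cusp",
                                  "condyle_left", "condyle_right"}

    def test_molar_cusp_sits_at_fossa_depth(self, dentition):
        _, _, landmarks = dentition
        assert landmarks["molar_cusp"][2] == pytest.approx(FOSSA_DEPTH)

    def test_meshes_are_finite_and_nonempty(self, dentition):
        for mesh in dentition[:2]:
            assert len(mesh.faces) > 0
            assert np.all(np.isfinite(mesh.vertices))


class TestEMG:
    def test_zero_noise_exactly_silent_outside_bursts(self, short_truth):
        rec = jt.synth_emg(short_truth, noise_amplitude=0.0, seed=1)
        t_cap = rec.times_ms - rec.sync_offset_ms
        for ch in EMG_CHANNELS:
            mask = np.zeros(rec.n_samples, dtype=bool)
            for on, off in short_truth.emg_burst_windows[ch]:
                mask |= (t_cap >= on) & (t_cap < off)
            assert np.all(rec.channels[ch][~mask] == 0.0)
            assert np.any(rec.channels[ch][mask] != 0.0)

    def test_five_emg_samples_per_capture_frame(self, short_truth):
        rec = jt.synth_emg(short_truth, sampling_hz=1000.0)
        assert rec.sampling_rate / short_truth.spec.frame_rate == 5.0

    def test_working_onset_precedes_balancing_by_construction(
            self, default_truth):
        for w, b in zip(default_truth.emg_burst_windows["masseter_working"],
                        default_truth.emg_burst_windows["masseter_balancing"]):
            assert w[0] < b[0]
            assert w[1] == b[1]  # both end at maximum closing

    def test_same_seed_identical(self, short_truth):
        a = jt.synth_emg(short_truth, seed=9)
        b = jt.synth_emg(short_truth, seed=9)
        for ch in a.channels:
            assert np.array_equal(a.channels[ch], b.channels[ch])
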