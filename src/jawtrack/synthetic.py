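"""Synthetic ground truth: jaw motion, marker captures, dentition, EMG.

Every downstream stage (pose estimation, registration, occlusion, phase
segmentation, EMG synchronization) is exercised against data generated
here, so the generator records the full ground truth alongside the data:
the exact pose per frame, the true phase-boundary frames, the true
occlusal-contact intervals, and the true EMG burst windows.

The motion model is a smooth periodic 6-DOF pose sequence built from
monotone-cubic (PCHIP) shape curves over a warped cycle phase ``w``:

* vertical translation: closure (0) at ``w = 0``, peak opening (``-gape``)
  at ``w = 0.5``, near-closure during the occlusal span ``w in [0.75, 1]``;
* antero-posterior translation and an asymmetric yaw derived from two
  condylar excursion curves — the working-side condyle reverses direction
  mid-opening while the balancing-side condyle keeps advancing until the
  end of opening, and both meet at the most posterior (symmetric) position
  at contact onset;
* a pitch (sagittal hinge) component proportional to opening depth;
* a lateral deviation toward the working side during opening, vanishing
  before contact.

The time warp ``w(u)`` places the four key timepoints at the fractions a
30-frame cycle needs for them to fall on frames 0 / 8 / 18 / 27 —
i.e. timepoints 1, 9, 19 and 28 of a 30-point cycle at 200 frames/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import trimesh
from scipy.interpolate import PchipInterpolator
from scipy.signal import butter, sosfiltfilt

from .core import CaptureSequence, LabeledPointSet, PoseSeries, RigidPose
from .errors import DegenerateGeometryError, InputError

# ---------------------------------------------------------------------------
# shared toy anatomy (CT frame, mm): +X anterior, +Y animal-left, +Z superior
# ---------------------------------------------------------------------------

#: half inter-condylar distance (mm)
CONDYLE_HALF_SPAN = 4.0
#: interdigitation depth of the molar cusp into its fossa groove (mm)
FOSSA_DEPTH = 0.1

#: named anatomical landmarks in the CT frame.  The molar mesiobuccal cusp
#: is on the right side, matching the default working side.
DEFAULT_LANDMARKS: dict[str, np.ndarray] = {
    "incisor_edge": np.array([4.0, 0.0, 0.0]),
    "molar_cusp": np.array([-3.5, -2.5, FOSSA_DEPTH]),
    "condyle_left": np.array([-8.0, CONDYLE_HALF_SPAN, 0.1]),
    "condyle_right": np.array([-8.0, -CONDYLE_HALF_SPAN, 0.1]),
}

#: 4-marker assembly bonded under the mandibular body (non-coplanar)
DEFAULT_MARKERS = LabeledPointSet(
    ("m1", "m2", "m3", "m4"),
    np.array([
        [2.0, 1.2, -1.6],
        [2.0, -1.2, -1.6],
        [-2.0, 1.2, -1.6],
        [-0.5, 0.0, -2.6],
    ]),
)

# timepoint fractions of the non-occlusal span: a 30-point cycle whose
# occlusal phase covers 3 points puts most-anterior at point 9, maximum
# opening at point 19 and working-masseter onset at point 25
_FRAC_ANTERIOR = 8.0 / 27.0
_FRAC_OPENING = 18.0 / 27.0
_FRAC_MASSETER_W = 24.0 / 27.0

EMG_CHANNELS = ("masseter_working", "masseter_balancing", "digastric")


@dataclass(frozen=True)
class MotionSpec:
    """Parameters of the synthetic masticatory motion.

    Defaults emulate ten successive chewing strokes recorded at
    200 frames/s with 150-ms cycles (30 points per cycle at 5-ms spacing).
    Gape and excursion magnitudes are plausible murine values and freely
    configurable.
    """

    n_cycles: int = 10
    cycle_ms: float = 150.0
    gape_mm: float = 2.0
    ap_excursion_mm: float = 1.5
    lateral_mm: float = 0.5
    occlusal_fraction: float = 0.1
    working_side: str = "right"
    frame_rate: float = 200.0
    pitch_rad: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.gape_mm, self.ap_excursion_mm, self.lateral_mm) < 0:
            raise InputError("motion magnitudes must be >= 0")
        if not (0 <= self.occlusal_fraction < 1):
            raise InputError("occlusal_fraction must be in [0, 1)")
        if self.cycle_ms <= 0 or self.frame_rate <= 0 or self.n_cycles < 1:
            raise InputError("cycle_ms, frame_rate, n_cycles must be positive")
        if self.working_side not in ("left", "right"):
            raise InputError("working_side must be 'left' or 'right'")

    @property
    def frames_per_cycle(self) -> float:
        return self.cycle_ms * self.frame_rate / 1000.0

    @property
    def n_frames(self) -> int:
        """Total frames: ``n_cycles`` full cycles plus the closing endpoint."""
        return int(round(self.n_cycles * self.frames_per_cycle)) + 1


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every synthetic motion."""

    spec: MotionSpec
    pose_series: PoseSeries
    #: per complete cycle: frame indices of the four key timepoints
    phase_boundaries: list[dict[str, int]]
    #: maximal contact runs (first_frame, last_frame), inclusive
    contact_frames: list[tuple[int, int]]
    #: per channel: list of (onset_ms, offset_ms) in capture time
    emg_burst_windows: dict[str, list[tuple[float, float]]]
    #: analytic minimum dentition clearance per frame (mm)
    clearance_mm: np.ndarray
    #: contact threshold used to derive contact_frames (mm)
    contact_threshold_mm: float
    #: landmark paths in the maxilla/CT frame, (n_frames, 3) each
    landmark_paths: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def molar_path(self) -> np.ndarray:
        return self.landmark_paths["molar_cusp"]


def _cycle_phase(spec: MotionSpec) -> tuple[np.ndarray, np.ndarray]:
    """Frame indices -> (cycle index, within-cycle fraction u in [0,1))."""
    i = np.arange(spec.n_frames, dtype=float)
    fpc = spec.frames_per_cycle
    cyc = np.floor(i / fpc + 1e-12)
    u = i / fpc - cyc
    u[u < 0] = 0.0
    return cyc.astype(int), u


def _warp(spec: MotionSpec) -> PchipInterpolator:
    """Monotone map u -> w placing key timepoints at w = 0.25/0.5/0.75."""
    occ = spec.occlusal_fraction
    up = 1.0 - occ
    u_knots = [0.0, _FRAC_ANTERIOR * up, _FRAC_OPENING * up]
    w_knots = [0.0, 0.25, 0.5]
    if occ > 1e-9:
        u_knots.append(up)
        w_knots.append(0.75)
    u_knots.append(1.0)
    w_knots.append(1.0)
    return PchipInterpolator(u_knots, w_knots)


def _shape_curves(spec: MotionSpec):
    """Return callables z(w), cw(w), cb(w), lateral s(w) on w in [0,1]."""
    g = spec.gape_mm
    z_occ = min(0.02, 0.01 * g)  # residual gap at contact-phase entry
    z_curve = PchipInterpolator([0.0, 0.5, 0.75, 1.0],
                                [0.0, -g, -z_occ, 0.0])
    cb_curve = PchipInterpolator([0.0, 0.5, 0.75, 1.0],
                                 [0.0, 1.0, -1.0, 0.0])

    def cw(w: np.ndarray) -> np.ndarray:
        return np.sin(2 * np.pi * w)

    def lat(w: np.ndarray) -> np.ndarray:
        return np.sin(np.pi * np.clip(w / 0.75, 0.0, 1.0)) ** 2

    return z_curve, cw, cb_curve, lat


def _pose_at(spec: MotionSpec, w: np.ndarray) -> list[RigidPose]:
    """Evaluate the 6-DOF pose at each warped phase value.

    The rotation combines the asymmetric yaw (condyle differential) with a
    pitch proportional to opening depth, both about the intercondylar
    midpoint; the translation is then solved so that the molar cusp
    follows its prescribed displacement exactly, which pins the molar
    extrema (and hence the key timepoints) to the warp knots.
    """
    z_curve, cw_f, cb_curve, lat_f = _shape_curves(spec)
    sign = -1.0 if spec.working_side == "right" else 1.0  # +Y is animal-left
    a = spec.ap_excursion_mm / 2.0
    z = z_curve(w)
    cw = cw_f(w)
    cb = cb_curve(w)
    molar = DEFAULT_LANDMARKS["molar_cusp"] if sign < 0 else \
        DEFAULT_LANDMARKS["molar_cusp"] * np.array([1.0, -1.0, 1.0])
    # with the molar pinned to its own path, a yaw about Z displaces the
    # balancing condyle by its lateral arm from the molar; dividing by
    # that arm makes the balancing condyle track cb (advancing through the
    # whole opening phase) while the working condyle, on a much shorter
    # arm, stays cw-dominated and reverses mid-opening
    balancing_arm = CONDYLE_HALF_SPAN + abs(molar[1])
    yaw = -sign * np.arcsin(
        np.clip(a * (cw - cb) / balancing_arm, -1.0, 1.0))
    pitch = (spec.pitch_rad * (-z) / spec.gape_mm
             if spec.gape_mm > 0 else np.zeros_like(z))
    molar_disp = np.column_stack([
        a * cw,
        sign * spec.lateral_mm * lat_f(w),
        z,
    ])
    poses = []
    for k in range(len(w)):
        cy, sy = np.cos(yaw[k]), np.sin(yaw[k])
        cp, sp = np.cos(pitch[k]), np.sin(pitch[k])
        Rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1.0]])
        Ry = np.array([[cp, 0, sp], [0, 1.0, 0], [-sp, 0, cp]])
        R = Rz @ Ry
        t = molar + molar_disp[k] - R @ molar
        poses.append(RigidPose(R, t))
    return poses


def _analytic_clearance(poses: list[RigidPose]) -> np.ndarray:
    """Exact dentition clearance per frame for the default toy anatomy.

    The closest features near closure are, by construction, the molar cusp
    apices against their fossa ceilings (plane z = FOSSA_DEPTH) and the
    incisor edge against the incisor shelf (plane z = 0); the vertical gap
    of the lowest of these is the exact mesh minimum distance whenever the
    apices stay within their groove footprints, which the default motion
    amplitudes guarantee.
    """
    cusp_r = DEFAULT_LANDMARKS["molar_cusp"]
    cusp_l = cusp_r * np.array([1.0, -1.0, 1.0])
    incisor = DEFAULT_LANDMARKS["incisor_edge"]
    out = np.empty(len(poses))
    for k, pose in enumerate(poses):
        gap_m = FOSSA_DEPTH - min(pose.apply(cusp_r)[2], pose.apply(cusp_l)[2])
        gap_i = 0.0 - pose.apply(incisor)[2]
        out[k] = max(0.0, min(gap_m, gap_i))
    return out


def _contact_runs(clearance: np.ndarray,
                  threshold: float) -> list[tuple[int, int]]:
    flags = clearance <= threshold
    runs: list[tuple[int, int]] = []
    start = None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(flags) - 1))
    return runs


def simulate_jaw_motion(spec: MotionSpec = MotionSpec(),
                        contact_threshold_mm: float = 0.05) -> SyntheticTruth:
    """Generate a ground-truth chewing motion from a :class:`MotionSpec`.

    Returns the exact pose sequence plus all derived truth: key-timepoint
    frames per cycle (recorded by an extrema scan of the generated molar
    path), analytic contact intervals, and EMG burst windows phase-locked
    to the motion (digastric through opening; working masseter from late
    closing; balancing masseter from contact onset; both masseters ending
    at maximum closing).
    """
    cyc, u = _cycle_phase(spec)
    w = np.asarray(_warp(spec)(u))
    poses = _pose_at(spec, w)
    series = PoseSeries(poses, spec.frame_rate,
                        np.zeros(spec.n_frames))
    paths = {
        name: np.stack([p.apply(pt) for p in poses])
        for name, pt in DEFAULT_LANDMARKS.items()
    }
    clearance = _analytic_clearance(poses)
    contact = _contact_runs(clearance, contact_threshold_mm)

    molar = paths["molar_cusp"]
    fpc = spec.frames_per_cycle
    starts = [int(round(k * fpc)) for k in range(spec.n_cycles + 1)]
    boundaries: list[dict[str, int]] = []
    still = spec.gape_mm == 0 and spec.ap_excursion_mm == 0
    if not still:
        for k in range(spec.n_cycles):
            s, e = starts[k], starts[k + 1]
            seg = slice(s, e + 1)
            z = molar[seg, 2]
            x = molar[seg, 0]
            max_closing = s + int(np.argmax(z[:-1]))  # endpoint belongs to next
            most_anterior = s + int(np.argmax(x))
            max_opening = s + int(np.argmin(z))
            rel = int(np.argmin(x[max_opening - s:]))
            most_posterior = max_opening + rel
            boundaries.append({
                "max_closing": max_closing,
                "most_anterior": most_anterior,
                "max_opening": max_opening,
                "most_posterior": most_posterior,
            })

    t_ms = 1000.0 / spec.frame_rate
    T = spec.cycle_ms
    up = 1.0 - spec.occlusal_fraction
    windows: dict[str, list[tuple[float, float]]] = {c: [] for c in EMG_CHANNELS}
    if not still:
        for k in range(spec.n_cycles):
            t0 = k * T
            windows["digastric"].append((t0, t0 + _FRAC_OPENING * up * T))
            windows["masseter_working"].append(
                (t0 + _FRAC_MASSETER_W * up * T, t0 + T))
            # balancing onset at true contact onset within this cycle
            lo = boundaries[k]["max_opening"]
            hi = starts[k + 1]
            onset_frame = next(
                (i for i in range(lo, hi + 1)
                 if clearance[i] <= contact_threshold_mm), hi)
            windows["masseter_balancing"].append(
                (onset_frame * t_ms, t0 + T))

    return SyntheticTruth(
        spec=spec,
        pose_series=series,
        phase_boundaries=boundaries,
        contact_frames=contact,
        emg_burst_windows=windows,
        clearance_mm=clearance,
        contact_threshold_mm=contact_threshold_mm,
        landmark_paths=paths,
    )


# ---------------------------------------------------------------------------
# marker capture
# ---------------------------------------------------------------------------

def synth_capture(truth: SyntheticTruth,
                  marker_geometry: LabeledPointSet = DEFAULT_MARKERS,
                  noise_sigma_mm: float = 0.0,
                  seed: int = 0) -> CaptureSequence:
    """Render the marker capture: pose applied to the marker geometry plus
    isotropic Gaussian noise.  Deterministic under a fixed seed."""
    if noise_sigma_mm < 0:
        raise InputError("noise_sigma_mm must be >= 0")
    pts = np.asarray(marker_geometry.points)
    if len(pts) < 3:
        raise DegenerateGeometryError("need >= 3 markers")
    centered = pts - pts.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[1] < 1e-6:
        raise DegenerateGeometryError("marker geometry is collinear")
    rng = np.random.default_rng(seed)
    frames = []
    for i, pose in enumerate(truth.pose_series.poses):
        obs = pose.apply(pts)
        if noise_sigma_mm > 0:
            obs = obs + rng.normal(0.0, noise_sigma_mm, obs.shape)
        frames.append(LabeledPointSet(marker_geometry.labels, obs, frame_id=i))
    return CaptureSequence(frames, truth.spec.frame_rate)


# ---------------------------------------------------------------------------
# toy dentition meshes
# ---------------------------------------------------------------------------

def _box(bounds_min, bounds_max) -> trimesh.Trimesh:
    lo = np.asarray(bounds_min, float)
    hi = np.asarray(bounds_max, float)
    m = trimesh.creation.box(extents=hi - lo)
    m.apply_translation((lo + hi) / 2.0)
    return m


def _refine(mesh: trimesh.Trimesh, max_edge: float) -> trimesh.Trimesh:
    v, f, _ = trimesh.remesh.subdivide_to_size(
        mesh.vertices, mesh.faces, max_edge=max_edge, return_index=True)
    return trimesh.Trimesh(vertices=v, faces=f, process=False)


def synth_dentition(resolution: float = 0.6):
    """Build toy mandible and maxilla meshes plus the landmark table.

    The maxilla carries an incisor shelf and, per side, a molar plate with
    an antero-posterior fossa groove (ceiling ``z = 0.1``); the mandible
    carries conical molar cusps and an incisor edge whose apices
    interdigitate with those features at the intercuspal pose with
    clearance exactly 0.  All contact-relevant features are exact geometric
    primitives (planes and cone apices), so clearances do not depend on the
    tessellation density; ``resolution`` (max edge length, mm) only
    controls how finely the surfaces are sampled with vertices.

    Returns
    -------
    mandible, maxilla : trimesh.Trimesh
    landmarks : dict[str, np.ndarray]
        ``incisor_edge``, ``molar_cusp``, ``condyle_left``, ``condyle_right``
        in the mesh (CT) frame.
    """
    # maxilla -------------------------------------------------------------
    parts = []
    for y0 in (2.5, -2.5):  # molar plates with groove (hole + ceiling)
        parts += [
            _box([-5.5, y0 + 0.5, 0], [-1.5, y0 + 1.25, 1]),   # lingual/buccal
            _box([-5.5, y0 - 1.25, 0], [-1.5, y0 - 0.5, 1]),
            _box([-5.5, y0 - 0.5, 0], [-4.7, y0 + 0.5, 1]),    # posterior wall
            _box([-2.3, y0 - 0.5, 0], [-1.5, y0 + 0.5, 1]),    # anterior wall
            _box([-4.7, y0 - 0.5, FOSSA_DEPTH], [-2.3, y0 + 0.5, 1]),  # ceiling
        ]
    parts.append(_box([3.0, -1.0, 0], [5.0, 1.0, 1]))          # incisor shelf
    parts.append(_box([-5.5, -4.0, 1], [5.0, 4.0, 2]))         # cranial body
    maxilla = trimesh.util.concatenate([_refine(p, resolution) for p in parts])

    # mandible ------------------------------------------------------------
    parts = [_box([-6.0, -3.5, -1.3], [4.5, 3.5, -0.3])]       # body plate
    for y0 in (2.5, -2.5):                                     # molar cusps
        cone = trimesh.creation.cone(radius=0.3, height=0.4, sections=24)
        cone.apply_translation([-3.5, y0, -0.3])
        parts.append(cone)
    inc = trimesh.creation.cone(radius=0.4, height=0.3, sections=24)
    inc.apply_translation([4.0, 0.0, -0.3])                    # incisor edge
    parts.append(inc)
    for y0 in (4.0, -4.0):                                     # rami + condyles
        parts.append(_box([-8.5, y0 - 0.5, -1.3], [-6.0, y0 + 0.5, -0.1]))
        ball = trimesh.creation.icosphere(subdivisions=2, radius=0.45)
        ball.apply_translation([-8.0, y0, 0.1])
        parts.append(ball)
    mandible = trimesh.util.concatenate(
        [_refine(p, resolution) for p in parts])

    return mandible, maxilla, {k: v.copy() for k, v in DEFAULT_LANDMARKS.items()}


# ---------------------------------------------------------------------------
# EMG
# ---------------------------------------------------------------------------

def synth_emg(truth: SyntheticTruth,
              channels: Sequence[str] = EMG_CHANNELS,
              sampling_hz: float = 1000.0,
              burst_amplitude: float = 100.0,
              noise_amplitude: float = 5.0,
              seed: int = 0,
              pre_roll_ms: float = 250.0,
              highpass_hz: float = 100.0):
    """Render phase-locked EMG bursts as band-limited noise (µV).

    Each channel is background Gaussian noise (high-passed at
    ``highpass_hz`` to mimic the recording chain) plus burst-amplitude
    noise gated to the truth windows of that channel.  The record starts
    ``pre_roll_ms`` before the capture, giving burst detectors a quiet
    baseline; the EMG-vs-capture clock offset is carried explicitly as
    ``sync_offset_ms = pre_roll_ms``.

    Returns an :class:`jawtrack.emg.EMGRecord`.
    """
    from .emg import EMGRecord  # local import to avoid a cycle

    if sampling_hz <= 2 * highpass_hz:
        raise InputError("sampling_hz must exceed twice the signal band")
    n_cap = len(truth.pose_series)
    dur_ms = (n_cap - 1) * 1000.0 / truth.spec.frame_rate
    n = int(round((pre_roll_ms + dur_ms + 50.0) * sampling_hz / 1000.0)) + 1
    t_ms = np.arange(n) * 1000.0 / sampling_hz
    rng = np.random.default_rng(seed)
    sos = butter(4, highpass_hz, btype="highpass", fs=sampling_hz,
                 output="sos")
    data: dict[str, np.ndarray] = {}
    for ch in channels:
        sig = np.zeros(n)
        if noise_amplitude > 0:
            sig = noise_amplitude * sosfiltfilt(sos, rng.standard_normal(n))
        if ch in truth.emg_burst_windows:
            burst = burst_amplitude * sosfiltfilt(sos, rng.standard_normal(n))
            mask = np.zeros(n, dtype=bool)
            for on, off in truth.emg_burst_windows[ch]:
                mask |= (t_ms >= on + pre_roll_ms) & (t_ms < off + pre_roll_ms)
            sig = sig + np.where(mask, burst, 0.0)
        data[ch] = sig
    return EMGRecord(channels=data, sampling_rate=sampling_hz,
                     sync_offset_ms=pre_roll_ms)
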