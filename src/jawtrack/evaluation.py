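"""System-evaluation protocols against simulated capture noise.

Two protocols mirror how optical jaw-tracking hardware is characterized:

* an accuracy grid — the marker assembly is commanded to every point of a
  cubic grid (default 3 mm extent in 0.5-mm steps, 7³ = 343 points
  including the origin), its position is re-estimated through the rigid
  pose pipeline under synthetic capture noise, and per-axis percent errors
  ``|measured − commanded| / |commanded| × 100`` are averaged over the
  nonzero commanded components;
* a step-resolution test — dwell–step–dwell sequences along each axis; a
  step is *resolved* when the measured displacement change exceeds the
  peak-to-peak fluctuation of the dwell segments.

Both run entirely in software; the printed accuracy of any physical
camera system is a property of that hardware, not of these protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LabeledPointSet, fit_rigid
from .errors import InputError
from .synthetic import DEFAULT_MARKERS

_AXES = ("x", "y", "z")


@dataclass
class CalibrationResult:
    """Per-axis accuracy-grid outcome."""

    #: per axis: (commanded mm, measured mm, percent error) rows
    per_axis: dict[str, np.ndarray]
    mean_percent_error: dict[str, float]
    grid_shape: tuple[int, int, int]

    @property
    def n_points(self) -> int:
        return int(np.prod(self.grid_shape))


def _measure_displacement(geometry: LabeledPointSet,
                          displacement: np.ndarray,
                          noise_sigma_mm: float,
                          rng: np.random.Generator) -> np.ndarray:
    obs = geometry.points + displacement
    if noise_sigma_mm > 0:
        obs = obs + rng.normal(0.0, noise_sigma_mm, obs.shape)
    pose, _ = fit_rigid(geometry,
                        LabeledPointSet(geometry.labels, obs))
    return pose.apply(geometry.points).mean(axis=0) \
        - geometry.points.mean(axis=0)


def accuracy_grid(extent_mm: float = 3.0,
                  step_mm: float = 0.5,
                  noise_sigma_mm: float = 0.0,
                  seed: int = 0,
                  geometry: LabeledPointSet = DEFAULT_MARKERS
                  ) -> CalibrationResult:
    """Run the cubic accuracy-grid protocol.

    The grid has ``(extent/step + 1)`` points per axis including the
    origin; the default 3 mm / 0.5 mm working volume enumerates 343
    points.  Zero commanded components are excluded from percent error
    (the relative error of a zero displacement is undefined).
    """
    if step_mm <= 0:
        raise InputError("step_mm must be > 0")
    n_side = extent_mm / step_mm
    if abs(n_side - round(n_side)) > 1e-9:
        raise InputError("extent_mm must be divisible by step_mm")
    n_side = int(round(n_side)) + 1
    rng = np.random.default_rng(seed)
    coords = np.arange(n_side) * step_mm
    rows: dict[str, list[tuple[float, float, float]]] = {a: [] for a in _AXES}
    for cx in coords:
        for cy in coords:
            for cz in coords:
                commanded = np.array([cx, cy, cz])
                measured = _measure_displacement(
                    geometry, commanded, noise_sigma_mm, rng)
                for k, axis in enumerate(_AXES):
                    if commanded[k] == 0:
                        continue
                    err = abs(measured[k] - commanded[k]) \
                        / abs(commanded[k]) * 100.0
                    rows[axis].append((commanded[k], measured[k], err))
    per_axis = {a: np.array(rows[a]) for a in _AXES}
    mean_err = {a: float(per_axis[a][:, 2].mean()) if len(per_axis[a])
                else 0.0 for a in _AXES}
    return CalibrationResult(per_axis, mean_err,
                             (n_side, n_side, n_side))


@dataclass
class ResolutionReport:
    """Per-axis dwell-step-dwell detectability."""

    step_mm: float
    resolved: dict[str, bool]
    displacement_change: dict[str, float]
    dwell_fluctuation: dict[str, float]

    @property
    def all_resolved(self) -> bool:
        return all(self.resolved.values())


def resolution_test(step_mm: float = 0.005,
                    noise_sigma_mm: float = 0.0,
                    n_dwell_frames: int = 50,
                    seed: int = 0,
                    geometry: LabeledPointSet = DEFAULT_MARKERS
                    ) -> ResolutionReport:
    """Dwell-step-dwell displacement resolution per axis.

    A step counts as resolved when the change in mean measured
    displacement between the two dwells exceeds the peak-to-peak
    fluctuation of the dwell segments.
    """
    if step_mm <= 0:
        raise InputError("step_mm must be > 0")
    rng = np.random.default_rng(seed)
    resolved, change, fluct = {}, {}, {}
    for k, axis in enumerate(_AXES):
        disp = np.zeros(3)
        pre = np.array([
            _measure_displacement(geometry, disp, noise_sigma_mm, rng)[k]
            for _ in range(n_dwell_frames)])
        disp = disp.copy()
        disp[k] = step_mm
        post = np.array([
            _measure_displacement(geometry, disp, noise_sigma_mm, rng)[k]
            for _ in range(n_dwell_frames)])
        delta = float(abs(post.mean() - pre.mean()))
        ptp = float(max(np.ptp(pre), np.ptp(post)))
        resolved[axis] = delta > ptp
        change[axis] = delta
        fluct[axis] = ptp
    return ResolutionReport(step_mm, resolved, change, fluct)


def min_resolvable_step(noise_sigma_mm: float,
                        n_dwell_frames: int = 50,
                        seed: int = 0,
                        lo_mm: float = 1e-4,
                        hi_mm: float = 1.0,
                        tol_mm: float = 1e-4,
                        geometry: LabeledPointSet = DEFAULT_MARKERS) -> float:
    """Smallest step resolved on all axes, found by bisection.

    The same seed is used at every evaluated step size (common random
    numbers), which makes detectability monotone in the step and the
    bisection well-posed; a direct sweep at the same seed gives the same
    answer.
    """
    def ok(step: float) -> bool:
        return resolution_test(step, noise_sigma_mm, n_dwell_frames,
                               seed, geometry).all_resolved

    if ok(lo_mm):
        return lo_mm
    if not ok(hi_mm):
        raise InputError("upper bound step not resolved; increase hi_mm")
    lo, hi = lo_mm, hi_mm
    while hi - lo > tol_mm:
        mid = 0.5 * (lo + hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi
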