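"""Masticatory-cycle segmentation from the molar trajectory.

Cycles are delimited by successive maxima of the molar's vertical (Z)
coordinate — the maximum jaw-closing positions.  Within each cycle the key
timepoints are: most anterior (max X), maximum opening (min Z), and most
posterior (min X after maximum opening).  The occlusal phase begins at the
first occlusal-contact frame at or after maximum opening; in normal
chewing this coincides with the most posterior position, and a consistency
flag records whether the two agree within a settable frame tolerance.

Phases partition each cycle::

    opening   [max_closing, max_opening)
    closing   [max_opening, occlusal_start)
    occlusal  [occlusal_start, next max_closing)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, medfilt

from .errors import InputError
from .integration import Trajectory
from .occlusion import OcclusionSeries

PHASE_NAMES = ("opening", "closing", "occlusal")


@dataclass
class CycleSegmentation:
    """Key timepoints and phase intervals of one chewing cycle."""

    max_closing: int
    most_anterior: int
    max_opening: int
    most_posterior: int
    cycle_end: int                      # next max-closing frame (exclusive)
    occlusal_start: int | None          # contact-onset frame, None if none
    flags: list[str] = field(default_factory=list)

    @property
    def phases(self) -> dict[str, tuple[int, int]]:
        """Half-open [start, end) frame intervals partitioning the cycle."""
        occ = self.occlusal_start if self.occlusal_start is not None \
            else self.cycle_end
        return {
            "opening": (self.max_closing, self.max_opening),
            "closing": (self.max_opening, occ),
            "occlusal": (occ, self.cycle_end),
        }


@dataclass
class PhaseSegmentation:
    """All detected cycles for one landmark trajectory."""

    cycles: list[CycleSegmentation]
    landmark: str
    frame_rate: float

    def __len__(self) -> int:
        return len(self.cycles)


def detect_key_timepoints(trajectory: Trajectory,
                          occlusion: OcclusionSeries | None = None,
                          min_prominence_fraction: float = 0.1,
                          consistency_tol_frames: int = 2,
                          median_prefilter: bool = False,
                          ) -> PhaseSegmentation:
    """Segment a molar trajectory into chewing cycles and phases.

    Parameters
    ----------
    trajectory
        Landmark path in the maxilla-fixed frame (normally the molar
        mesiobuccal cusp).
    occlusion
        Per-frame contact series; if None, the occlusal phase is anchored
        at the most posterior point and flagged ``no_contact_data``.
    min_prominence_fraction
        Minimum peak prominence for cycle-delimiting Z maxima, as a
        fraction of the observed gape (Z range); rejects jitter maxima.
    consistency_tol_frames
        Tolerance for the ``contact onset == most posterior`` check.
    median_prefilter
        Apply a 3-frame median filter before extremum detection.
    """
    pts = trajectory.points
    if np.isnan(pts).all():
        raise InputError("trajectory has no valid frames")
    x = pts[:, 0].copy()
    z = pts[:, 2].copy()
    if median_prefilter:
        x = medfilt(x, 3)
        z = medfilt(z, 3)
    gape = np.nanmax(z) - np.nanmin(z)
    if gape <= 0:
        raise InputError("flat trajectory: no cycles detectable")
    prom = min_prominence_fraction * gape
    # sentinel padding lets the first/last frames qualify as cycle maxima
    pad = np.nanmin(z) - 2 * prom
    zp = np.concatenate(([pad], np.nan_to_num(z, nan=pad), [pad]))
    peaks = find_peaks(zp, prominence=prom)[0] - 1
    if len(peaks) < 2:
        raise InputError("no complete chewing cycle found")

    if occlusion is not None and len(occlusion) != len(trajectory):
        raise InputError("occlusion series length mismatch")
    contact = occlusion.contact if occlusion is not None else None

    cycles = []
    for s, e in zip(peaks[:-1], peaks[1:]):
        seg_x = x[s:e + 1]
        seg_z = z[s:e + 1]
        flags: list[str] = []
        most_anterior = s + int(np.nanargmax(seg_x))
        max_opening = s + int(np.nanargmin(seg_z))
        most_posterior = max_opening + int(np.nanargmin(seg_x[max_opening - s:]))
        if np.nanmax(seg_x) - np.nanmin(seg_x) < 1e-12:
            flags.append("degenerate_ap")  # pure vertical open-close
            most_anterior = s
            most_posterior = max_opening
        occl = None
        if contact is not None:
            hits = np.flatnonzero(contact[max_opening:e + 1])
            if hits.size:
                occl = max_opening + int(hits[0])
                if abs(occl - most_posterior) > consistency_tol_frames:
                    flags.append("contact_posterior_mismatch")
            else:
                flags.append("no_contact_in_cycle")
        else:
            occl = most_posterior
            flags.append("no_contact_data")
        if occl is not None:
            occl = min(occl, int(e))
        if not (s <= most_anterior <= max_opening <= most_posterior <= e):
            flags.append("order_violation")
        cycles.append(CycleSegmentation(
            max_closing=int(s),
            most_anterior=most_anterior,
            max_opening=max_opening,
            most_posterior=most_posterior,
            cycle_end=int(e),
            occlusal_start=occl,
            flags=flags,
        ))
    return PhaseSegmentation(cycles, trajectory.landmark,
                             trajectory.frame_rate)


def phase_statistics(segmentation: PhaseSegmentation,
                     frame_rate: float | None = None) -> dict:
    """Per-phase durations (ms) per cycle, with mean ± SD across cycles.

    SD uses the n-1 denominator and is reported as None for a single
    cycle.  Phase durations sum exactly to the cycle duration.
    """
    fps = frame_rate or segmentation.frame_rate
    if fps <= 0:
        raise InputError("frame rate must be positive")
    dt = 1000.0 / fps
    per_cycle = []
    for c in segmentation.cycles:
        durs = {name: (b - a) * dt for name, (a, b) in c.phases.items()}
        durs["cycle"] = (c.cycle_end - c.max_closing) * dt
        per_cycle.append(durs)
    summary = {}
    for key in PHASE_NAMES + ("cycle",):
        vals = np.array([d[key] for d in per_cycle])
        summary[key] = {
            "mean_ms": float(vals.mean()) if len(vals) else None,
            "sd_ms": float(vals.std(ddof=1)) if len(vals) > 1 else None,
        }
    return {"per_cycle_ms": per_cycle, "summary": summary,
            "n_cycles": len(per_cycle)}
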