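"""Estimate per-frame 6-DOF mandible poses from a synthetic marker capture.

Generates ten chewing cycles, renders the four mandible markers with
2-µm capture noise, fits one rigid pose per frame, and compares the
recovered poses with the generator's ground truth.
"""

import numpy as np

import jawtrack as jt

truth = jt.simulate_jaw_motion(jt.MotionSpec())
capture = jt.synth_capture(truth, noise_sigma_mm=0.002, seed=1)
series = jt.estimate_pose_series(capture, jt.DEFAULT_MARKERS)

rot_err = [np.linalg.norm(est.rotation - exp.rotation)
           for est, exp in zip(series.poses, truth.pose_series.poses)]
tr_err = [np.linalg.norm(est.translation - exp.translation)
          for est, exp in zip(series.poses, truth.pose_series.poses)]

print(f"frames tracked:          {len(series)}")
print(f"mean fit RMSD:           {np.nanmean(series.residual_rmsd):.6f} mm")
print(f"mean rotation error:     {np.mean(rot_err):.2e} (Frobenius)")
print(f"mean translation error:  {np.mean(tr_err):.2e} mm")

# The fit RMSD reflects the injected marker noise (~2 µm); rotation and
# translation errors of a few µm show the 4-marker fit recovering the
# full 6-DOF pose at instrument-level accuracy.
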