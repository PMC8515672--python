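"""Segment chewing cycles into phases and synchronize EMG bursts.

The masticatory cycle divides into opening (maximum closing to maximum
opening), closing (to contact onset) and occlusal (contact to the next
maximum closing).  Masseter and digastric bursts are detected from the
high-passed, rectified, RMS-enveloped signals and aligned to capture
frames through the recorded clock offset.
"""

import jawtrack as jt

truth = jt.simulate_jaw_motion(jt.MotionSpec())
traj = jt.Trajectory("molar_cusp", truth.molar_path, 200.0)
occ = jt.OcclusionSeries(truth.clearance_mm, 0.05, 200.0)

seg = jt.detect_key_timepoints(traj, occ)
stats = jt.phase_statistics(seg)
print(f"cycles detected: {len(seg)}")
for name in ("opening", "closing", "occlusal", "cycle"):
    s = stats["summary"][name]
    print(f"  {name:9s} {s['mean_ms']:6.1f} ms  (SD {s['sd_ms']:.1f})")

record = jt.synth_emg(truth, seed=0)
bursts = jt.detect_bursts(jt.preprocess(record))
aligned = jt.align_to_frames(bursts, 200.0, record.sync_offset_ms)

c0 = seg.cycles[1]
print(f"\ncycle 2 timepoints (frames): closing max {c0.max_closing}, "
      f"most anterior {c0.most_anterior}, opening max {c0.max_opening}, "
      f"most posterior {c0.most_posterior}, contact {c0.occlusal_start}")
work = aligned["masseter_working"][1]
bal = aligned["masseter_balancing"][1]
dig = aligned["digastric"][1]
print(f"digastric burst:          frames {dig['onset_frame']}"
      f"-{dig['offset_frame']} (opening phase)")
print(f"working masseter onset:   frame {work['onset_frame']} (late closing)")
print(f"balancing masseter onset: frame {bal['onset_frame']}"
      f" (= contact onset {c0.occlusal_start})")

# The working-side masseter fires several frames before its balancing
# counterpart; the balancing onset coincides with occlusal contact —
# the coordination pattern that shapes the asymmetric condylar paths.
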