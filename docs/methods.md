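# Methods

## Rigid pose estimation

The mandible is treated as a rigid body carrying ≥3 labeled markers
(4 by default).  Per frame, the pose minimizing the sum of squared
marker distances is computed in closed form: both point sets are
centered on their centroids, the cross-covariance `H = Aᵀ B` is
decomposed by SVD, and `R = V diag(1, 1, det(VUᵀ)) Uᵀ` — the
determinant correction guarantees a proper rotation even when noise
would make the unconstrained optimum a reflection.  The per-frame
residual RMSD is reported; for isotropic marker noise σ and n markers
its expectation obeys `E[RMSD²] = σ²(3n−6)/n`, which the tests use as a
Monte-Carlo oracle.

Identifiability requires the centered marker configuration to have rank
≥ 2; a configuration whose second singular value falls below 1e-6 mm is
rejected as collinear rather than silently producing an arbitrary
rotation.  Frames with missing (non-finite) markers are fit on the
remaining markers when at least three survive, otherwise flagged
invalid and carried as gaps; optional gap filling interpolates linearly
on translation and spherically (slerp) on rotation.  Orthonormality,
round-trip and rigidity checks all use a 1e-9 tolerance.

Coordinates are right-handed anatomical axes — +X anterior, +Y
animal-left, +Z superior — with mm and ms as units and frame rates in
Hz.

## Maxilla registration and landmark trajectories

Because the head is rigidly restrained, the maxilla is static in
capture coordinates, and a single registration suffices: at a
consolidated acquisition with the jaws fixed in the intercuspal
position, the same 4-marker fit yields the CT→capture pose of the whole
cranium.  A mandibular landmark `q` (CT frame) then traces
`P_max⁻¹ ∘ P_t (q)` — motion relative to the maxilla, expressed in a
frame axis-aligned with the CT anatomical axes so the sagittal (X, Z),
frontal (Y, Z) and occlusal (X, Y) projections are orthographic drops
of one coordinate.  This output frame is invariant to any global rigid
change of capture coordinates (verified to 1e-9 in the tests).
Trajectory smoothing is off by default; an optional centered
moving-average is provided.

## Occlusal clearance

Clearance between the posed mandible and the static maxilla uses the
symmetric vertex-to-surface metric: minimum over (posed mandible
vertices vs maxilla triangles) and (maxilla vertices vs posed mandible
triangles).  The query is exact: the nearest-vertex distance gives a
global upper bound `b`; every (point, triangle) pair that could beat
`b` must have a triangle centroid within `b + r_max` of the point
(`r_max` = largest centroid-to-vertex radius), and all such pairs are
evaluated with exact point–triangle distances.  The reverse direction
reuses the static mandible KD-trees by mapping maxilla vertices through
the inverse pose.  Tests verify equality with an exhaustive
all-pairs scan (independently implemented scalar point–triangle
routine) to 1e-9 mm on random small meshes.

Interpenetrating meshes report clearance 0.  Containment is tested only
for the few query vertices nearest the other mesh (full point-in-mesh
scans per frame are prohibitive); in dentition scenes penetration
happens at the closest features, so this is adequate, but deep
penetration far from the metric's closest pair would be missed — a
documented limitation.  Penetration depth is deliberately out of scope.

A region filter (`molar`, `incisor`) restricts mandible faces to those
within a radius (default 1.5 mm) of the matching landmarks, mirrored
across the midline so both molar rows count.

Contact is flagged where clearance ≤ threshold (default 0.05 mm).  The
threshold is a mesh-scale convention, not a measured quantity: optical
systems judge contact visually, and no numeric threshold can be proven
equivalent to that judgment.

## Phase segmentation

Cycles are delimited by successive maxima of the molar's Z coordinate
(maximum jaw closing), found with a prominence filter of 10% of the
observed gape to ignore jitter; sentinel padding lets the first and
last frames qualify as cycle boundaries.  Within a cycle: most anterior
= max X; maximum opening = min Z; most posterior = min X at or after
maximum opening; ties break to the earliest frame, and a cycle with no
AP excursion is flagged degenerate.  The occlusal phase starts at the
first contact frame at or after maximum opening; in normal chewing this
coincides with the most posterior position, and a flag records
disagreement beyond a settable tolerance (default 2 frames).  Phases
partition each cycle exactly: opening [max closing, max opening),
closing [max opening, contact onset), occlusal [contact onset, next max
closing).  An optional 3-frame median prefilter is off by default.

Extrema are taken on the raw trajectory.  A local parabolic refinement
was evaluated and rejected: the asymmetrically warped cycle biases the
vertex estimate, and it performed worse than the raw argmax.  Note the
information limit near maximum opening: on the default motion the molar
Z changes only 0.34 µm between the frames adjacent to the true minimum,
so at instrument-level noise (µm scale) that one boundary is
recoverable only to ±2 frames — the well-curved boundaries (≥11 µm per
frame) recover to ±1.

## EMG processing

Preprocessing follows the standard fine-wire chain: zero-phase
(forward–backward) 4th-order Butterworth high-pass at 100 Hz, full-wave
rectification, and a centered moving-RMS envelope (default 10 ms).
Bursts are maximal runs with envelope above `baseline mean + k·SD`
(baseline = first 200 ms, k = 3 by default) lasting ≥10 ms, with runs
separated by less than that merged.  A flat zero baseline falls back to
k × the global envelope SD and is flagged.

Burst *edges* need care: the centered RMS window crosses threshold half
a window before signal energy starts and past its end, and contiguous
near-threshold noise can extend a run further.  For bursts well above
threshold the edges are therefore estimated as the crossings of half
the burst's median envelope — for a centered window on an abrupt-onset
burst this estimator's bias is about a quarter window, comfortably
inside the ±5 ms edge accuracy the synthetic studies demonstrate.
Marginal bursts fall back to run edges shrunk by half a window per
side, which also discards single-spike excursions whose run spans
exactly one window; with this rule pure-noise records of 1 s produce a
spurious burst in well under 5% of runs at k = 3.  Because a noise
burst can genuinely open with a few quiet samples, edge errors have
irreducible stochastic tails; the package reports edges, not
guarantees.

Synchronization is an explicit signed offset (EMG clock minus capture
clock); burst edges map to frames as
`floor((t − offset) · rate / 1000)`, negative times clipping to frame 0
with a flag.

## Synthetic data generator

The generator defines the study conditions: ten 150-ms chewing cycles
(30 frames per cycle at 200 frames/s, 5 ms apart), 2-mm gape, 1.5-mm
antero-posterior excursion, 0.5-mm lateral deviation, a 10% occlusal
fraction, right working side, 1000-Hz EMG.  Gape and excursion
magnitudes are plausible murine values chosen once; they are not stated
by any measurement and are freely configurable.

Motion model: a monotone (PCHIP) time warp `w(u)` maps cycle fraction
to a canonical phase in which the four key timepoints sit at
w = 0, 0.25, 0.5, 0.75; the warp knots are placed so a 30-frame cycle
puts them on frames 0/8/18/27 (timepoints 1/9/19/28 of a 30-point
numbering).  On `w`, vertical molar displacement descends from closure
to −gape at w = 0.5 and returns to within 0.02 mm of closure across the
occlusal span; AP displacement is `(ap/2)·sin 2πw`; lateral deviation
is a bump supported on opening only.  The rotation combines a
hinge-like pitch proportional to opening depth (default 0.4 rad at full
gape, chosen so the condyles translate nearly parallel to the occlusal
plane) with an asymmetric yaw derived from two condylar excursion
curves — the working condyle reverses direction mid-opening while the
balancing condyle advances to the end of opening; the translation is
then solved so the molar cusp follows its prescribed path exactly,
pinning the key-timepoint extrema.  Recorded truth: exact poses,
per-cycle boundary frames from an extrema scan of the generated molar
path, analytic contact intervals, and EMG burst windows (digastric
through opening; working masseter from the 24/27 point of the
non-occlusal span; balancing masseter from contact onset; both ending
at maximum closing).

Marker captures add isotropic Gaussian noise (default studies use
σ = 2 µm, consistent with a system whose displacement resolution is
below 5 µm).  EMG channels are Gaussian noise high-passed at 100 Hz,
gated to the truth windows at 100 µV against a 5-µV background, with a
250-ms quiet pre-roll carried as the sync offset.

The toy dentition is built from exact geometric primitives: planar
plates, an antero-posterior fossa groove per side (ceiling 0.1 mm into
the plate), conical molar cusps and an incisor edge whose apices are
mesh vertices touching their counterparts at the intercuspal pose with
clearance exactly 0.  Because the contact-relevant features are exact
at any tessellation density, the default maximum edge length is 0.6 mm
(a `resolution` parameter refines it); clearance accuracy does not
depend on it, only surface sampling density does.  The groove is wide
enough (±1.2 mm AP, ±0.5 mm lateral) that the cusp stays inside its
footprint throughout the default motion, which is what makes the
generator's analytic clearance exact near contact.

What the generator does *not* emulate: soft tissue and marker-fixture
flex, camera-model distortions and occlusion dropouts, anatomically
realistic murine skull geometry, ramped (non-abrupt) EMG burst onsets,
amplitude variation across cycles, and chewing-side alternation.
Passing tests therefore demonstrate the correctness of the
reconstruction and detection machinery under the stated noise model,
not robustness to those real-world effects.

## Evaluation protocols

The accuracy grid commands the marker assembly to every node of a cubic
grid (extent/step + 1 per axis, 343 points for 3 mm at 0.5-mm steps,
origin included), re-estimates each position through the rigid-fit
pipeline under capture noise, and averages per-axis percent errors
`|measured − commanded| / |commanded| × 100` over nonzero commanded
components (zero displacements have no defined relative error and are
excluded).  The resolution test runs dwell–step–dwell sequences per
axis; a step is resolved when the change in mean measured displacement
exceeds the peak-to-peak fluctuation of the dwell segments.  A
bisection finds the smallest resolvable step under common random
numbers, which makes detectability monotone in step size.  Printed
accuracy figures of any physical camera system characterize that
hardware; these protocols reproduce the procedure, not the numbers.

## Problem sizes and determinism

Default analyses run ten cycles (301 frames); tests use two-to-three
cycle studies and coarser tessellations where the geometry permits, and
the acceptance script uses the full defaults (1000 fit instances, the
343-point grid, 27-condition phase sweep, 100 EMG ordering runs,
200 false-positive runs).  All randomness flows from explicit seeds;
identical config and seed reproduce byte-identical JSON reports.  The
phase-recovery sweep uses noiseless captures — it validates the full
capture→pose→trajectory→segmentation path across the motion-parameter
grid, while noise robustness of boundary detection is characterized
separately (see the information limit above).
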