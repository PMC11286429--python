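# Methods

## Problem setting

A camera is carried past a crop row at constant speed and fruit is
detected in every frame; counting is performed by tracking each fruit
across frames and tallying distinct track identities.  In the camera
frame every fruit moves in near-uniform linear motion (the vehicle's
speed dominates), but occlusion by leaves, fruit overlap and camera
shake intermittently hide fruit and displace it from its predicted
course.  Both effects break motion-based association and cause identity
switches, each of which double-counts a fruit.  The pipeline combines an
online tracker biased toward appearance evidence with an offline track
repair pass.

## Motion model

Each track carries an 8-dimensional state (cx, cy, a, h, vcx, vcy, va,
vh): box center (px), aspect ratio w/h (dimensionless), height (px) and
their per-frame derivatives.  The transition matrix is block
constant-velocity with a unit time step (one frame); the measurement
matrix selects the first four components.  Camera ego-motion is not
modeled separately: the shared horizontal drift is absorbed by each
track's velocity state, and the control input is identically zero.

Noise is height-proportional so gating behaves identically for near and
far fruit: position-like process/measurement standard deviations are
`h/20` and velocity-like ones `h/160` per frame; the dimensionless
aspect channel uses fixed small constants (process 1e-2, velocity 1e-5,
measurement 1e-1).  A new track initializes at the measurement with zero
velocity and a deliberately wide velocity prior (10× the velocity
noise), so two or three updates suffice to lock onto the true course.
The Kalman gain is computed through a Cholesky factorization of the
innovation covariance rather than an explicit inverse; covariances are
re-symmetrized after every step and stay positive semidefinite over
thousands of cycles (property-tested).

## Online association

Per frame, four stages run in order:

1. **Prediction** for every live track.
2. **Cascade matching** over confirmed tracks, one assignment per
   time-since-update level (most recently seen first), so a track missed
   for one frame can never lose a detection to one missed for ten.  The
   cost is the minimum cosine distance between the detection embedding
   and the track's gallery (budget 100, oldest evicted); pairs whose
   squared Mahalanobis distance exceeds the χ² 0.95 quantile at 4 dof
   (9.4877) are infeasible.  Acceptance threshold: cosine distance 0.2.
   A config weight can blend motion distance into the cost; the default
   keeps appearance as the sole cost with motion as a hard gate, which
   is what "emphasize appearance" means operationally here.
3. **IOU matching** (threshold IOU ≥ 0.3) for tentative tracks and
   confirmed tracks missed exactly one frame — young tracks have
   galleries too thin for appearance to be reliable.
4. **Appearance re-matching** for detections still unclaimed against
   confirmed tracks that failed stages 2–3 this frame (1 ≤
   time-since-update ≤ max_age).  No motion gate — the premise is that
   the motion state has mutated — and a stricter cosine threshold of
   0.15 guards against false re-attachment.  A re-matched track keeps
   its identity, gallery and history, but its Kalman state is
   re-initialized from the new detection with zero velocity: the old
   motion estimate is untrusted by construction.  The stage runs last so
   it only sees genuinely motion-orphaned pairs, and bridged gap frames
   are not back-filled online (the offline pass may interpolate).

Lifecycle: tracks confirm after 3 consecutive hits, die immediately if
tentative when missed, and die after 30 missed frames (1 s at 30 fps)
when confirmed.  Detections below confidence 0.3 are dropped at ingest,
as are degenerate (non-positive size) boxes.  Assignment is the
Hungarian algorithm; equal-cost ties are broken toward the
lexicographically smallest (track, detection) pair by an additive
perturbation of order 1e-12/(T·D), far below any meaningful cost
difference, making runs bit-reproducible.

## Offline track optimization

Finalized segments are repaired in three steps.

*Stability.*  For each segment the per-frame cosine similarity to the
segment's unit mean embedding is computed; the segment is unstable if it
is shorter than 5 frames or the similarity variance exceeds 0.05,
partially stable for variance in (0.01, 0.05], else stable.  Unstable
segments — blinking false positives, incoherent fragments — are removed
from counting but kept in an audit log; partially stable segments are
counted but never merged.  The three-way split and both variance
thresholds are package choices: only the principle (eliminate by
appearance-similarity variance) is fixed by the method, not the values.

*Pair vote.*  For two stable, temporally disjoint segments of M and N
frames with a gap of at most 45 frames, all M×N pairwise cosine
similarities are computed and entries ≥ 0.8 count as votes; the pair is
eligible only if votes strictly exceed M·N/2.  A gap of zero frames
covers the continuous-switch case and a positive gap the fragment case —
one mechanism, two regimes.

*Position and shape.*  The earlier segment's mean per-frame center
velocity extrapolates its last box across the gap; the pair passes if
the normalized center distance (Euclidean center distance over the mean
of the two box diagonals) to the later segment's first box is ≤ 1.0 and
the width and height ratios (larger/smaller) are ≤ 1.5.  The
mean-diagonal normalization makes the tolerance scale-free; 1.0 unit is
deliberately permissive because the motion mutations being repaired are
themselves tens of pixels.

Merging is greedy in ascending gap order (ties: higher mean pairwise
similarity, then lower id), linearly interpolates the gap in
top-left/width/height space (interpolated frames are flagged, and their
embeddings are the renormalized linear blend of the endpoints), keeps
the earlier segment's id, and re-enters the merged segment into the
pool until a fixpoint.  The pass never increases the identity count and
is idempotent (both property-tested).

## Evaluation metrics

CLEAR-MOT with the canonical matching protocol: previous-frame pairings
persist while both boxes exist and overlap at IOU ≥ 0.5; remaining boxes
are assigned by maximal overlap; unmatched predictions are false
positives, unmatched truths false negatives; a truth whose assigned
prediction id differs from its last known assignment (including across
gaps) counts one identity switch.  MOTA = (1 − (FP+FN+IDSW)/GT)·100.
MOTP is reported as the mean IOU of matched pairs ×100: the per-match
distance is read as an overlap similarity, which is the interpretation
consistent with tracking-precision values in the high-80s percent; a
normalized-center-distance variant is available via `motp_mode`.

Counting over videos: ACP = 100·mean(1 − |GT−COUNT|/GT), MAE =
mean |GT−COUNT|, RMSE = √mean (GT−COUNT)².  Reports round to two
decimals; full precision is kept internally.  Precision/recall count
arithmetic is provided as a utility; mAP over real imagery is out of
scope (it requires the detector and images).

## Synthetic scenarios

The generator emulates the survey statistics the tracker relies on —
uniform linear motion, identity-clustered unit embeddings, detection
dropout, box jitter (2 px position, 3% size by default), uniform false
positives, and occlusion events that simultaneously suppress detections,
multiply embedding noise (×5), and offset the subsequent trajectory by a
motion jolt (~45 px by default).  The jolt is essential: with exact
uniform linear motion a constant-velocity filter bridges any pure
detection gap, so identity switches would never arise without it.

Presets encode three survey conditions of increasing difficulty — 57
fruits / 360 frames, 95 / 510 and 96 / 600 (12, 17 and 20 s at 30 fps),
with dropout rising with density and embedding noise with darkness — and
an occlusion suite of 20 seeded 150-frame, 12-fruit scenarios with six
events each, used for the 2×2 ablation of re-matching × offline merging.
These sizes keep the full suite and ablation within a couple of minutes
on one core while leaving dozens of switch opportunities per
configuration.

What the simulator does **not** model: photometric appearance (embeddings
are synthetic unit vectors, not CNN features), correlated detector
failures, perspective scale change, fruit on moving branches, and
duplicate detections of one fruit.  Passing tests therefore demonstrate
the correctness and the qualitative benefit of the tracking machinery
under the stated statistical assumptions, not detector-specific
performance on real orchard video.

## Numerical and design notes

- IOU computes both areas from the same edge coordinates as the
  intersection, so identical boxes score exactly 1.0 despite
  floating-point cancellation; the ratio is clamped at 1.
- The infeasible-cost sentinel is a large finite value (1e5) excluded by
  the acceptance threshold, keeping the assignment solver
  implementation-agnostic.
- Boxes are continuous throughout; MOT files serialize at 2 decimals,
  the only rounding in the pipeline.
- Published-style aggregate figures are rounded half-up at two decimals
  (so 88.125 → 88.13), avoiding banker's-rounding artifacts in reports.
- Frames are 1-based at every file boundary (MOT convention).

## Known limitations

- The appearance re-matching stage trusts embeddings absolutely within
  its threshold; two nearly identical fruits lost simultaneously can in
  principle swap identities, which no motion gate prevents at that
  stage.
- Offline merging is greedy, not globally optimal; pathological segment
  sets could merge in a suboptimal order (the fixpoint iteration
  mitigates chains).
- The evaluator and tracker share the package's IOU/assignment
  primitives; tests therefore cross-check both against independent
  brute-force implementations.
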