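# Methods

This note documents the models and numerical choices behind `zfmotor`:
what the pipeline computes, what the synthetic-data generator does and
does not emulate, and where design decisions were genuinely open.

## Coordinate and angle conventions

Coordinates are image-style: 0-based (y, x) pixels with y increasing
downward.  "Up" therefore means decreasing y.  Heading is the angle of
the center→snout vector with 0° = up and positive angles toward +x;
angles are wrapped into (−180°, 180°].  Keypoint roles are fixed by
index: snout = 0, body center = 2 (≈30% of the arc, the swim-bladder
region), caudal tip = 7.  The default pixel pitch is 37.8 µm/px for both
plate formats, derived from the platform's printed pixel↔micrometre
pairs (1.84 px = 69.59 µm; 3.52 px = 133.12 µm); it is configurable.

## Windowing and egocentric alignment

Windows are 40 frames (250 ms at 160 fps), stride 1.  A track of *T*
frames yields *T* − 40 windows — deliberately one fewer than the *T* −
40 + 1 full windows that exist, reproducing the published pipeline shape
(1,600 frames → 1,560 windows).  The dropped final window only shifts
the covered range by one frame; the majority vote fills the last frame
from its nearest covered neighbour.

Alignment is a single rigid transform per window: rotate about the
first-frame center so the center→snout vector points up, then translate
that center to the origin, applied identically to all 40 frames.  Two
invariants characterize it exactly and are enforced in tests to 1e-9:
all within-frame pairwise keypoint distances are preserved, and
pre-composing the raw window with any global rotation + translation
leaves the aligned output unchanged.  A window whose first-frame
center–snout distance is below 1e-12 px cannot define a rotation; it is
center-translated only and flagged degenerate.

Normalization is dataset-affine: scale = max |coordinate| over the
aligned training set (max of absolute values, since coordinates are
signed after alignment), offset = mean of the scaled coordinates; apply
= x/scale − offset.  The constants are fitted on training data only,
frozen into the model bundle, and differ between plate formats.
Flattening is a frame-major C-order reshape to length 640, recorded in
the bundle manifest so the layout stays stable.

## Kinematics

Per-frame series are derived from the track: heading (center→snout),
heading change (wrapped absolute difference, in [0°, 180°]), speed
(center-keypoint displacement × pixel pitch × fps, mm/s; the center is
used because it is least affected by tail beat), and signed tail angle
(center→tip vs the body axis; 0 for a straight fish).  Frame 0 and
degenerate frames carry NaN, which propagates rather than being
interpolated.

`compute_kinematics` optionally applies a centered moving average to the
coordinates before differencing (`smooth_frames`, default 1 = off; the
bout census uses 5 frames = 31 ms).  Under white per-frame tracking
noise the raw frame-to-frame speed is dominated by jitter (σ = 70 µm at
160 fps contributes tens of mm/s of apparent speed); the moving average
leaves any linear trajectory exactly unchanged while shrinking the
jitter term.  Consequently, the 2 mm/s spontaneous speed-bout rule
(speed > threshold for ≥ 5 frames; the 5 mm/s variant from the source
figure is exposed as an override) is only meaningful on smoothed or
low-noise tracks; on raw simulator output at full noise it saturates.

## Semi-supervised model

Clip mining: KMeans with k = 9 (seed 2023) over normalized feature
vectors.  A cluster is flagged stationary when its members' mean net
within-window center displacement is < 0.5 mm.  Net displacement
replaces summed path length here because path length integrates noise
(~5 mm per window at σ = 70 µm even for a motionless fish), which would
make any threshold vacuous.  Identical duplicated inputs (fewer distinct
vectors than k) are rejected rather than silently producing degenerate
clusters.

Supervised model: per plate format, PCA retaining 95% of training
variance (seed 2023, whitening off, full SVD solver) followed by a
100-tree random forest (seed 2023, unlimited depth — forest
hyper-parameters are not pinned by any external constant, so common
defaults are used and recorded in the bundle).  The split is stratified
90/10 per class, implemented directly (each class permuted and cut to
within one clip of the target fraction, with at least one clip per class
on each side) so that 2-clip classes still appear in both subsets.
Evaluation reports the row-normalized confusion matrix and micro, macro
and weighted F1 — all three, because which average an "overall F1"
refers to is ambiguous.

The 24-well class set is {stationary, scoot, turn, AsLB, VsLB}; the
96-well set merges scoot and turn into "movement".  Model bundles
serialize the normalizer constants, PCA basis, forest, class order,
window layout and config; a save → load round trip reproduces
predictions bitwise.

## Ethogram, bouts and response rates

Majority voting assigns frame *t* the most frequent call among the
(up to 40) windows whose span contains *t*.  Exact ties break by a fixed
class priority — VsLB > AsLB > turn > scoot > movement > stationary —
i.e. rarer, stimulus-locked classes win, so a startle call is never
silently dropped on a tie.  On the fully covered interior (frames seen
by all 40 windows) voting provably cannot leave an isolated single-frame
label and, empirically over thousands of random call sequences, never
increases the number of label transitions relative to naively placing
each window's call at its start frame.  Both properties can fail within
the first/last W − 1 frames, where fewer windows vote; tests therefore
assert them on the interior.

Call bouts are maximal same-label runs of **strictly more than** 5
frames ("exceeded" read as >, configurable); the speed-bout rule is "at
least" 5 frames — the two thresholds are intentionally distinct.  Bout
runs are counted in post-vote frames, not raw windows.  Responder
definitions: a trial responds when ≥ 1 frame inside [onset, onset +
window) carries the elicited class (250 ms for taps, 1.0 s for dark
flashes — windows that exceed the established response latencies); a
fish responds when any of its replicate trials does (a logical OR, not a
rate comparison).

## Synthetic-data generator

The generator exists so the pipeline can be trained and tested without
the proprietary recordings.  It emulates: 10 s acquisitions at 160 fps
(1,600 frames); 8 midline keypoints placed along a bend-parameterized
chain (body length 3.7 mm, arc fractions 0, .12, .30, .45, .60, .75,
.88, 1 — the instrument does not tabulate keypoint positions, so these
are a design choice with the center keypoint at the swim-bladder
region); per-format white Gaussian position noise calibrated so the RMS
deviation per coordinate equals the measured keypoint placement error
(69.59 µm / 133.12 µm); specular reflection at the well wall (radius 7.8
mm / 3.45 mm) to keep fish in-well without modelling thigmotaxis; and a
slow mean-reverting resting tail-curvature wander (amplitude 4–12°,
~0.5 s timescale), because real larvae are never perfectly straight and
a simulator without postural variability concentrates the PCA variance
budget into a handful of gross-trajectory modes, which is not how real
pose data behaves.

Class templates drive per-frame speed, signed heading change and tail
bend.  Defaults (all configurable per segment):

| class | heading change | peak speed | duration | notes |
|---|---|---|---|---|
| stationary | 0 | 0.05 mm/s drift | — | posture wander only |
| scoot | < 20° total wobble | 8 mm/s (5–12 in corpus) | 0.20 s | 25 Hz tail beat |
| turn | 30–90° smooth ramp | 3 mm/s | 0.16 s | shortest maneuver |
| AsLB | 90–140°, ~90% within 4 frames | 35–60 mm/s, burst starts with the bend | 0.12–0.18 s | latency < 15 ms from stimulus |
| VsLB | 140–180° over ~60% of the bout | 18–30 mm/s, ramping after the bend | 0.20–0.28 s | latency 150–500 ms |

These magnitudes respect the reported *orderings* between classes
(startle classes exceed scoot/turn in max speed and |Δheading| by ≥ 5×;
turns are briefest; visual startles are larger and later than acoustic
ones) but are otherwise free simulator parameters, not measurements of
real fish.

Training corpora default to the published class counts (24-well:
66 stationary / 102 scoots / 75 turns / 60 AsLB / 137 VsLB = 440 clips;
96-well: 432 stationary / 486 movement / 170 AsLB / 309 VsLB = 1,397).
Each clip is cut from a longer simulated bout at a random phase —
emulating how sliding-window mining catches behaviors at arbitrary
offsets — under reviewer-faithful constraints: at least ~100 ms of the
behavior is inside the clip, startle clips contain the C-/O-bend onset
(a reviewer identifies startles by the initial bend; a mid-burst
fragment would not be labelled startle), and scoot/turn clips contain
the bout's peak-speed core (a low-speed tail fragment reads as
stationary).  The 96-well "movement" class mixes scoot and turn
kinematics at 60/40.

What the generator does **not** emulate: hydrodynamics, wall-following
(thigmotaxis), habituation across trials, the ~200-odd behaviors beyond
these five classes (e.g. seizure-like events, long- vs short-latency
startle variants), temporally correlated tracking error, and occlusion
dropouts.  Passing tests therefore show the pipeline's machinery is
correct and recovers the classes *it simulates*; they do not certify
classification accuracy on real recordings, which requires the original
labelled clips.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale by design: corpora at
the published class counts, response recovery with 24 fish × 6 trials of
10 s each, oracle equivalence over 1,000 random sequences per primitive.
All randomness flows through explicit `numpy.random.Generator` seeds;
the forest runs single-threaded (`n_jobs=1`) so full-chain reruns with
identical seeds are byte-identical.

## Known limitations

* The real instrument's NetCDF variable naming is proprietary; the
  schema here (group per well, `keypoints(time, point, axis)`) is this
  package's own documented dialect.
* Held-out F1 on the synthetic corpora varies by a few points with the
  corpus seed (macro ≈ 0.95–1.0): with 0.95-variance PCA, part of the
  AsLB/VsLB distinction lives in low-variance components, and the
  smallest class holds only 6 held-out clips, so one error moves its
  recall by 17 points.
* Spontaneous speed-bout detection needs coordinate smoothing at
  realistic noise (see Kinematics above).
* Gap validation interpolates linearly and cannot reconstruct fast
  maneuvers lost to long tracking dropouts; runs longer than `max_gap`
  reject the track instead.
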