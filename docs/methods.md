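# Methods

This note documents the models, parameters, numerical choices and
limitations of the `gma` pipeline, in the order the data flows through it.

## Measurement model and preprocessing

The pipeline assumes an overhead camera parallel to the crib surface, a
unicolor sheet, and a supine infant whose whole body stays in frame.
Frames are converted to grayscale with BT.601 luma weights (any fixed
convention works because the binarization threshold *T* is tuned per
video). Two binary streams are derived per frame:

- **background difference** `|frame − background| ≥ T` → body silhouette;
- **interframe difference** `|frame_l − frame_{l−1}| ≥ T` → moving pixels
  (all-zero for the first frame, which has no predecessor).

Comparisons use the absolute difference and an *inclusive* threshold, so
binarization is idempotent on binary input and raising *T* never adds
foreground pixels. How the background image is obtained is a deployment
question; the package accepts an explicit empty-crib frame, a constant
brightness level, or falls back to the per-pixel temporal median of the
sequence. No morphological cleanup is applied by default; a 3×3 opening is
available behind `morphological_opening`.

## Segmentation

A least-squares ellipse (scikit-image's conic fit) is fitted to the outer
boundary pixels of the largest connected silhouette component — boundary
pixels rather than all pixels because the conic fit is a contour model, and
the largest component for robustness to speckle. The fit happens once per
recording on the first usable frame; the areas then stay fixed, which
matches the per-interval index design (a refit-per-frame mode would change
the areas mid-interval). Degenerate fits (< 6 boundary points, non-elliptic
conic) raise a typed error.

The analysis area *A* is the circumscribed rectangle of the ellipse
expanded by margins `a1 = t_a1·α` (head end), `a2 = t_a2·α` (foot end) and
`a3 = t_a3·β` (both sides), clipped to the frame. Split lines are realized
axis-aligned in image coordinates: the recording protocol aligns the infant
with the frame, and the head end is user-supplied (`head_end` ∈ top /
bottom / left / right) — there is no automatic head detection. The row or
column at a split belongs to the head-/left-side region (half-open
convention), which makes the quadrants `A_1..A_4` an *exact* partition of
`A_9`; the partition identity is asserted in the tests on every frame.
"Left" and "right" are the infant's own: a supine infant faces the camera,
so with the head at the image top the infant's left is the image right.

## Feature extraction

Per frame and area: posture `P_l` (silhouette pixel count) and movement
`M_l` (changed-silhouette-pixel count divided by the reference area
`P_ave`). Changed pixels are counted between the background-difference
masks of adjacent frames (their symmetric difference); the
interframe-difference image stream is retained for display parity but is
not the source of `M`. Both terms of the changed-pixel count use the same
area `A_k` — a mixed-area reading would be ill-defined for `k ≠ 9`.

`P_ave` summarizes the whole-body area over the first *E* = 10 frames; the
default reading is the *mean* of `P_9` over those frames (stable), with the
*max* reading behind `p_ave_mode="max"`. The body centre is the silhouette
centroid in `A_9`; frames with an empty silhouette carry the last valid
centre forward (logged) instead of propagating NaN into the velocity and
fluctuation signals. Velocity `G^v` and fluctuation `G^d` are normalized by
`√P_ave`, making all centre signals dimensionless and body-size invariant;
`G^v_1 = (0,0)` by contract, and `G^d` is centred on the analysis-interval
mean (so it sums to zero over the interval).

Smoothing uses second-order low-pass Butterworth filters: cutoff
`f_cut_m = 10 Hz` for the movement series and `f_cut_g = 5 Hz` for the
centre trajectory (velocity and fluctuation are derived from the smoothed
trajectory; both are linear in it, so the order does not matter beyond the
first-frame contract). Filtering is zero-phase (forward–backward) by
default so per-frame indices do not lag; offline analysis permits this, and
a single causal pass is available.

## The 25 indices

Defaults: interval length *L* = 900 frames (30 s at `f_s` = 30 Hz), step
*S* = *L* (non-overlapping; *S* = 1 gives the sliding mode), movement
threshold `M_th = 0.05` (fraction of body area changing per frame),
analysis band 0–`f_max` = 5 Hz, rhythm subinterval `L_f` = 300 frames
(*L*/*L_f* must be an integer), FFT window 128 samples with 127 overlap,
symmetry correlation window 300 with 299 overlap.

Conventions and degenerate cases, all tested:

- `I1` counts frames with `M ≥ M_th` (inclusive, matching the detector);
  `I2` is 0 when no frame is supra-threshold; an `I3` episode still active
  at the interval end is counted once (end clipped to *L*).
- `I4`/`I5` are the upper/lower ratios of `I1` and `I2` respectively and
  are 0 when the denominator is 0. (`I5` is the ratio of `I2`; a printed
  formula that repeats the `I1` ratio is treated as a copy error, per its
  own description.)
- `I6` is the mean of zero-lag Pearson correlations over sliding 300-point
  windows (step 1); zero-variance windows are skipped and logged, and an
  interval with no valid window yields 0.
- Rhythm pairs (`I7`/`I8`, `I9`/`I10`, `I11`/`I12`): each subinterval's PSD
  is estimated Welch-style (periodic Hann taper, per-segment mean removal,
  averaged one-sided periodograms) and normalized by its maximum — the
  normalization cancels in the spectral moments but matches the exported
  display spectra. The centre index is the mean of per-subinterval centre
  frequencies; the companion index is the mean of the *reciprocals* of the
  per-subinterval second moments (the operational definition), with the
  across-subinterval standard deviation of the centre frequency available
  as `spread_mode="sd"`. All-zero spectra (static scenes) are skipped;
  if every subinterval is degenerate the pair is (0, 0), flagged in the
  log, so a static recording yields an all-zero index vector.
  Mean removal before the PSD is deliberate: without it the DC line
  dominates every spectrum and the centre frequency collapses toward 0.
- `I13`/`I14` are mean *absolute* values of `G^v`/`G^d` per axis
  ("total magnitude"); a signed mean would cancel for oscillatory motion
  and is available behind `signed=True` for comparison.

The 25-entry ordering is fixed (`INDEX_NAMES`) so canonicalization
parameters are positionally stable across runs and files.

## Classifier

Canonicalization standardizes each index against the mean/SD of a
normal-GM reference group (WM+FM rows of the training table by default);
zero-variance reference indices are an error naming the index.

The LLGMN expands the canonicalized input to its quadratic monomials
`[1, z, z_i z_j (i ≤ j)]`, assigns each (class, component) a linear score,
applies a softmax over all components (one component's weights pinned to
zero for identifiability), and sums component posteriors within a class.
Each component thereby realizes a Gaussian density up to a shared
normalizer, so the network expresses exact Gaussian-mixture posteriors; on
shared-covariance data with one component per class (the default) it can
represent the Bayes posterior exactly, which the tests verify against the
closed form. Training maximizes the penalized teacher log-likelihood with
L-BFGS from a small seeded random initialization; non-convergence within
`max_iter` (default 500) is a logged warning, returning the best-so-far
weights. The ridge penalty (`l2`, default 1.0 on the summed-likelihood
scale) is essential at clinical sample sizes — tens of intervals per class
against a 351-term expansion — and also keeps the KL information strictly
positive for feature selection. The objective is convex in the weights up
to the softmax over components, and batch training makes the fit invariant
to sample order.

Interval classification averages the per-step posteriors (one step per
index vector; many in sliding mode), then applies the entropy gate on the
averaged posterior: `S > S_th` (default 1, natural log) → Type 0. The
movement gate — upper- or lower-body `I1 = 0` → Type 0 — takes precedence
in the reported rejection reason, and uses the same interval's `I1`.
A per-step-entropy variant is behind a flag; entropy base is configurable
(the uniform-posterior rejection at `S_th = 1` is unchanged under base 2).

A leave-one-out harness mirrors the evaluation protocol (31 samples/class,
repeated over seeded draws). On 4-class spherical-Gaussian synthetic index
data the suite requires LOO accuracy within 5 points of the Monte-Carlo
Bayes rate; the default test separation (3.5σ along one axis per class,
Bayes accuracy ≈ 98%) puts the problem in the regime where n = 124 LOO is
an accurate estimate — at much lower separations *no* classifier tracks the
Bayes rate that tightly from 124 samples (the gap is estimator variance,
not model error; linear-discriminant and logistic baselines behave the
same).

## Feature selection

`K(Q, C)` is operationalized as the teacher–posterior KL summed over
evaluation samples; with one-hot teachers this is `Σ_n −ln Y_true`, clamped
at ε = 1e-12 (logged). `G_[i]` retrains the model *without* index i (not
input-zeroing) and takes the ratio of the reduced to the base K. Backward
elimination removes, each round, the index with `|G − 1|` smallest; ties go
to the larger canonical position (determinism); a perfect base fit
(`K = 0`, unreachable with the default ridge) falls back to accuracy-drop
ranking, logged. Training accuracy on the evaluation set (16/class by
convention) is recorded at every remaining-index count.

On the bundled construction — 6 informative indices whose class means are
±2 sign patterns from mutually orthogonal rows (equal pairwise distances,
so every informative index carries non-redundant information) plus 19 pure
noise indices — the 19 noise indices are eliminated first in ≥ 90% of
seeded repetitions and the accuracy curve stays flat until only informative
indices remain. With weaker separation the informative indices become
partially redundant given one another and can legitimately interleave with
the last noise removals; the construction's amplitude is chosen so the
contrast in G is decisive.

## Synthetic data generator

`generate_video` renders an elliptical trunk with four limb discs on a
unicolor background: per-limb stroke frequency, stroke length, duty cycle,
optional sinusoidal body-centre drift, and i.i.d. Gaussian pixel noise
clipped to [0, 255] (exercising the binarization threshold without
modelling a camera). Defaults emulate the recording protocol: 720×480 at
30 Hz, a 300×150 px trunk, 30 s takes, bright body on a dark sheet, 2
brightness units of noise; tests use smaller frames and bodies, which scale
all extracted quantities without changing any contract.

Limb kinematics are *strokes*: within each period the disc sweeps with
speed envelope `(1 − cos 2πft)/2` and reverses at the zero-speed instants.
The extracted movement signal `M` is proportional to the sweep speed, so
its fundamental sits exactly at the nominal frequency *f* — a sinusoidal
*position* would put the power of `|velocity|` at 2*f* and leave the
planted frequency unrecoverable in principle. Ground truth (limb
frequencies, noiseless silhouette centroid and area per frame, trunk path)
is emitted alongside and serializes to JSON.

What the generator does **not** emulate: limb occlusion by the trunk or
blanket, non-rigid deformation, illumination gradients, shadows, camera
jitter, and the textured appearance of real video. Consequently the
rendered blobs change far fewer pixels per frame than a real limb of the
same size: the default scenarios stay below the clinical movement threshold
`M_th = 0.05`, so synthetic `I1–I3` are exercised directly at the series
level rather than through rendered video. Passing tests demonstrate the
correctness of the *computations* and the recoverability of planted
kinematics — not classification performance on clinical recordings, which
requires clinical data.

`generate_index_samples` draws labelled Gaussian index vectors per class
(Cholesky sampling; non-PD covariances are an error naming the class), and
`bayes_accuracy` Monte-Carlo-estimates the optimal classifier's accuracy
from the true densities as an independent oracle.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen to exercise
every code path with comfortable statistical margins: 240×320 synthetic
videos of 900 frames for rhythm recovery and partition checks, 120×160 ×
60-frame videos for end-to-end determinism, LOO at 31/class × 5
repetitions, backward elimination at 16/class × 10 repetitions, and 100
random fixtures per equation-level oracle comparison.

## Known limitations

- Split lines are axis-aligned; a strongly rotated infant would need the
  rotation-aware area mode that is deliberately not implemented (the
  protocol aligns the infant).
- The ellipse is fitted once per recording; gross posture changes across a
  long recording are better served by re-running analysis per segment.
- Crying/sleeping periods are excluded via a user-supplied interval mask,
  not detected automatically.
- Only the four observed GM types are classified; rarer abnormal types
  (chaotic, abnormal fidgety) are out of scope, as is any claim about
  clinical accuracy.
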