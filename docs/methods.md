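# Methods

This note records the models behind `jointcoord`, the conventions and
defaults that matter for interpreting its numbers, and what the
synthetic generators do and do not emulate.

## Data model

A *repetition* is a strictly increasing time vector (seconds) plus a
T×n matrix of joint angles; a *dataset* is a named list of repetitions
sharing a joint list and an angle unit (`deg` or `rad`).  Repetitions
may differ in duration: the contribution metric ignores timing
entirely, and the synchronization metric resamples each repetition to
a common percent-of-movement axis.  Rows with missing cells are
dropped at load time, never imputed.  The time column is optional when
only the PCA-based metric is wanted.

Centering subtracts each joint's grand mean over **all repetitions
pooled** (not per-repetition means), because the reference PCA is
computed on the pooled samples and must see the same offsets.
Amplitudes are deliberately not rescaled: a joint that moves more
should carry more variance.  Centering is idempotent and removes
constant starting-posture offsets exactly.

## JcvPCA

PCA is computed by SVD of the pooled centered sample matrix with
1/(N−1) variance normalization — numerically safer than forming the
covariance explicitly.  Eigenvector sign is fixed by making each row's
largest-magnitude coefficient positive; the choice is irrelevant after
absolute values but makes frames reproducible and self-comparison
tests exact.

The metric subtracts reference weights from reprojected comparison
weights, `|b^A| − |a|`, so that **positive = joint more used in the
comparison dataset**.  Properties worth knowing:

- `jcvpca(ds, ds) = 0` exactly; all entries lie in [−1, 1].
- The re-PCA on reprojected data has the same spectrum as a direct
  PCA of the comparison dataset (orthonormal change of basis).
- When all n components are retained the change of basis is lossless
  and the metric is antisymmetric in the dataset order; retaining
  m < n components truncates the comparison data to the reference
  subspace, which is where the direction of comparison genuinely
  matters.  The reference should always be the baseline condition.
- `m` defaults to task_dof + 1 when a task DoF count is supplied
  (task components plus one null-space component), else to n.

Optional explained-variance weighting multiplies each row by the
**reference frame's explained-variance ratio** (not raw variances):
ratios keep the weighted deltas inside [−1, 1] and make rows
summable into a single change score.  A warning (not an error) is
emitted when the pooled sample count falls below 5 samples per
variable, the usual lower bound of the variable-to-factor guidance;
`bootstrap_stability` resamples repetitions with replacement and
reports the worst row-wise eigenvector deviation as a direct
stability check.

## JsvCRP

Range normalization maps min → −1 and max → +1 exactly, per joint and
**per repetition** (each movement normalized on its own range,
matching the per-movement phase-portrait construction).  Velocities
are estimated by central differences with second-order one-sided
endpoints before normalization, then normalized separately.

The phase angle is the two-argument arctangent `atan2(vel, pos)` in
(−π, π] — a one-argument tangent would lose quadrants.  Note that
under this portrait convention the phase of an oscillation *decreases*
along the cycle (the portrait is traversed clockwise), so in
`CRP = φⱼ − φᵢ` a joint that lags in time carries the larger phase; a
constant positive CRP for "second joint leads" holds under the
opposite (counterclockwise) convention.  Sign conventions cancel in
the area metric, which is what the package reports.

Wrap policy: by default wrapped phases are subtracted and the
difference re-wrapped into (−π, π]; phase unwrapping before
subtraction is available (`unwrap=True`) and removes ±2π jumps at the
cost of an arbitrary 2π branch offset.  The wrapped default is used
throughout the tests.

Degenerate joints: if the caller-supplied noise range exceeds a
joint's range of motion, the joint's normalized position, velocity and
phase are all set identically to zero and the joint is flagged
non-contributing — the hypothesis being that a noise-dominated joint
does not synchronize with anything.  The guard threshold (ratio > 1)
is deliberately conservative; callers should pass their sensor's noise
range (the reaching examples use 0.5°, a generous bound for joint
encoders).

Time normalization interpolates linearly onto G = 101 points
(0, 1, …, 100 %).  An optional dynamic-time-warping mode aligns a
curve to a reference repetition before resampling, for datasets whose
movement phases occupy very different fractions of the duration; the
DTW is a plain O(N²) dynamic program intended for already-resampled
curves.  Mean curves pool all repetitions and targets of a dataset by
default (a per-target mode exists).

The area uses the trapezoidal rule.  On the normalized axis its unit
is angle × percent-of-movement (`deg*%` for degree data — CRP values
converted to degrees on output); with `normalize_time=False` (all
repetitions on one time base, e.g. single simulated signals) the unit
is angle × seconds.  Grid refinement from G = 101 to 1001 changes
smooth-curve areas by well under 1 %.

## Natural variability

The baseline condition's repetitions are shuffled (seeded generator)
and partitioned into two disjoint halves — without replacement, the
reference half taking the extra repetition when the count is odd —
the metric is computed between halves, and the split is repeated
`n_splits` times (default 15).  Per-entry mean, SD and SE = SD/√n_splits
are reported; the SE interpretation adapts the
standard-error-over-subjects rule to splits.  The default exceedance
rule is mean ± SE, with mean ± SD available; boundary values count as
inside.  Whether published dispersions of this kind are SDs or SEs is
often ambiguous — this package reports both.

## Synthetic generators

**Two-sine pair.**  θ₁ = sin(2πft) in both datasets; θ₂ doubles the
amplitude and lags by 1 rad (A) or π/2 (B).  Defaults: f = 1 Hz, 5 s
(whole periods, so sample moments match analytic sinusoid moments
exactly), 100 Hz, no noise.  With these inputs every intermediate is
closed-form: A's covariance is [[0.5, cos 1], [cos 1, 2]] with
eigenvalues 2.1743/0.3257, B's joints are uncorrelated, both CRP
curves are constants (1 and π/2), and the area is |π/2 − 1| per second
of record.  The 5 s duration is a typical slow-movement record length;
the published variant of this comparison used an unspecified sampling
grid, so printed magnitudes differ while every sign and structural
feature is reproduced.

**Reaching simulator.**  A planar two-link arm: shoulder flexion θ₁
measured from vertical-down, elbow flexion θ₂ as the interior angle
(180° = straight), hand height relative to the shoulder

    h = −L₁ cos θ₁ − L₂ cos(θ₁ + (180° − θ₂)),

with L₁ = 0.30 m, L₂ = 0.28 m (adult segment lengths).  The task:
from rest (θ₁ = 0°, θ₂ = 140°) reach target heights (−0.15, 0, +0.15) m,
five repetitions each, 2 s per movement at 100 Hz.  The hand-height
course follows a minimum-jerk profile — the standard smoothness model
for point-to-point reaching; any smooth sigmoid would serve.  Joint
excursions are solved per repetition (bracketed root-finding on the
forward kinematics) from the jittered start posture so every
repetition ends on its target.

Strategies:

- *physiological* — shoulder and elbow move together with a fixed
  sharing ratio (elbow 0.25° per shoulder degree, extension) and a
  proximal-to-distal lead: shoulder active over the first 85 % of the
  movement, elbow over the last 85 %.  The sharing ratio is a
  shoulder-dominant stand-in for an unknown human ratio; it also
  bounds the elbow's reference PC weight (≈ 0.24), which caps how
  large elbow-contribution *drops* can appear against this baseline.
- *desync* — identical start/end postures, strictly sequential: all
  shoulder motion in the first half, all elbow motion in the second.
  An idealized desynchronization; human attempts at this task tend to
  increase elbow amplitude involuntarily, which this simulator does
  not emulate — so the simulator's elbow contribution *falls* slightly
  where a human's rose.
- *shoulder_only* — elbow held at its start angle (plus sensor noise),
  shoulder solves the height alone.
- *elbow_overuse* — shoulder repeats its physiological trajectory; the
  elbow flexes quickly by 15° during the first 20 % of the movement,
  then performs one large extension to the same final angle,
  synchronized with the shoulder's rise.  The early-flexion/late-
  extension shape is what makes the elbow's *correlated* amplitude —
  and hence its leading-PC weight — larger than baseline; a
  mid-movement detour of the same size would load on the second
  component instead.

Per-repetition variability: start-posture jitter (SD 1°), duration
jitter (±10 %), white measurement noise (SD 0.05°, an encoder-scale
figure).  What the simulator does **not** emulate: muscle dynamics,
signal-dependent noise, movement corrections/submovements, trial-to-
trial learning, soft-tissue artifacts, and the involuntary strategy
leakage of real subjects.  Passing tests on these data therefore
demonstrate the metrics' algebra and sensitivity, not their behavior
on every idiosyncrasy of recorded human movement.

## Problem sizes and determinism

Default problem sizes (500-sample sine datasets; 15 repetitions of
~200 samples per reaching condition; 15 splits) keep the full test
suite and the acceptance script in the low seconds.  All randomness
flows from explicit integer seeds through `numpy.random.default_rng`;
equal seeds give byte-identical datasets.

## Known limitations

- The CRP sign interpretation depends on the phase-portrait
  orientation convention (see above); compare only curves computed
  with the same convention.
- Range-normalized CRP is unreliable for joints with minor
  participation; the noise guard is a blunt instrument (all-or-
  nothing per joint).
- The reprojection-based contribution metric is designed for
  *variations* of a strategy; for entirely different strategies the
  truncated reprojection can hide information, and a direct PCA-to-PCA
  comparison (out of scope here) may be preferable.
- Thresholds from split-half resampling describe one subject/session;
  pooling across subjects is not implemented.
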