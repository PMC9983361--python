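# Methods

This note documents the models, defaults and design choices behind
`rigipose`: a pipeline that predicts the four non-remotable MDS-UPDRS III
items (Rig-UE, Rig-LE, Rig-Neck, PS; each ordinal 0–3) from 2-D keypoint
time series of eleven remotely performable motions.

## Keypoint preprocessing

Input is OpenPose-style per-frame keypoints (`BODY_25`, `HAND_21`), each
joint an `(x, y, confidence)` triplet in image pixels (origin top-left,
y downward), nominally at 20 fps. Cleaning rules, all configurable in
`PreprocessConfig`:

* confidence < **0.3** → sample treated as missing;
* interior missing runs ≤ **5 frames** (0.25 s at 20 fps) → linear
  interpolation; longer runs and edge runs are held at the nearest valid
  sample, so a clean recording never contains residual gaps;
* a required joint missing in > **30%** of frames rejects the recording
  (the required set defaults to the joints the motion's channels touch);
* coordinates are divided by the **median trunk length** (Neck–MidHip), or
  the median wrist-to-middle-knuckle length for hand-only recordings, and
  the vertical axis is flipped so anatomical "up" is positive. This makes
  every downstream feature invariant to camera distance and image
  resolution; preprocessing is idempotent on gap-free inputs.
* several detected people in a frame → the one with the largest mean
  bounding-box area is kept (the patient is the subject closest to the
  camera in a tele-assessment).

The thresholds are engineering choices tuned to tolerate brief occlusions;
no clinical source specifies them.

## Channel map

Each motion contributes a small set of scalar channels chosen to cover the
joints that passive rigidity testing manipulates and the sway axes relevant
to balance: tap aperture (FT), fingertip–wrist aperture (HM), knuckle-line
orientation (PSOH), big-toe height (TT), toe height + knee angle (LA),
mid-hip height + trunk orientation (AFC), ankle excursion + ankle angle +
arm swing per side (GAIT), neck/hip horizontal sway + trunk orientation
(POS), 3–10 Hz band-passed index-fingertip displacement (PTOH/KTOH), and
all 46 facial action-unit intensity series (FE). Angles are computed in
the image plane — consistent with a single-RGB-camera pipeline, and
accepting the projection error that entails.

## Smoothing and cycle structure

Channels are smoothed with a cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`). The spline is fitted against
the *frame index* rather than seconds: the GCV search for the penalty is
parameterised for unit-spaced abscissae and collapses oscillatory signals
at sub-second spacing. `smooth_signal` selects the penalty by generalized
cross-validation by default; the feature pipeline instead fixes
`lam = 0.05` (frame-index units), which at 20 fps attenuates keypoint
jitter while preserving voluntary cycle amplitude to within about 1% and
avoids re-running the GCV optimisation on every channel of every subject.

Peaks and valleys are located with `scipy.signal.find_peaks` under two
rules: prominence ≥ **0.25 ×** the signal's interquartile range (its
peak-to-peak range when the IQR vanishes), and same-type spacing ≥
**0.5 / dominant frequency**, the dominant frequency being the spectral
argmax of the detrended signal in 0.5–10 Hz. This rejects tremor ripple
riding on voluntary cycles. Same-type runs are resolved by keeping the
most prominent member, so surviving peaks and valleys alternate.
Extremum positions and values are refined with a three-point parabola:
sampled extrema underestimate cycle amplitude by up to ~5% at ten samples
per cycle, and the vertex correction removes most of that bias.

## Feature families

* **Kinematic** (per cyclic channel): per-cycle amplitude = refined peak
  minus adjacent (preceding, else following) valley; per-cycle frequency =
  reciprocal peak-to-peak interval; each summarised by mean/max/min; mean
  rising and falling speed (amplitude over half-cycle duration);
  **decrement** = least-squares slope of cycle amplitude against cycle
  index; **hesitations** = cycles longer than 1.5 × the median cycle
  duration. Fewer than two cycles zeroes everything and sets a
  `kin_degenerate` flag.
* **Time domain**: max, min, range (= range of motion for angle
  channels), 5/25/50/75/95% quantiles, SD, RMS, absolute mean, skewness,
  excess kurtosis; zero-variance inputs report 0 with a flag.
* **Frequency domain** (detrended, Hann-windowed FFT): dominant frequency
  in 0.5–10 Hz and its power, total band power, band-power fractions for
  0.5–3 Hz (voluntary movement) and 3–10 Hz (tremor), and spectral entropy
  normalised to [0, 1]; constant signals are flagged with zero powers.

A feature's *family* is kinematic if it is a cycle statistic, otherwise
the kind of its channel (position or angle; AU channels count as
position). Facial-expression channels skip the kinematic family — no
cyclic structure is assumed in expression intensity.

Left/right channels are aggregated into mean, max, min across sides and
|right − left| before modelling; unsided channels pass through. Missing
feature values are zero-filled, with the validity flags left in the matrix
so tree models can split on validity.

Per-target motion sets: Rig-UE {FT, HM, PSOH, AFC, PTOH, KTOH, GAIT};
Rig-LE {LA, AFC, GAIT, TT}; PS adds POS; Rig-Neck uses all eleven.

## Scoring models

One LightGBM multiclass booster per target item, wrapped in sklearn-style
estimators. Defaults (all configurable): softmax objective over 4 classes,
31 leaves, learning rate 0.1, 200 trees, ≥ 5 samples per leaf, feature and
bagging fractions 0.9 with fixed seeds, deterministic single-threaded
training so the same data and seed reproduce the model (and its gain
vector) bit for bit. These are small-cohort-safe defaults; no published
values exist for this problem. The rare score of 4 is merged into 3
before training (too few subjects at the top of the scale). The predicted
score is the argmax-probability class; exact ties resolve to the *lower*
class (the conservative clinical choice).

**Feature selection.** Features are ranked once by total split gain of a
model trained on all features of the training set; for each candidate
count k in the grid (default 5, 10, …, 50), leave-one-out CV retrains on
the fixed top-k set and the pooled out-of-fold ACC±0 and weighted kappa
are recorded. The chosen k maximises (ACC±0, kappa) lexicographically,
preferring smaller k on full ties; the final model is refit on all
training subjects with the chosen features. Ranking once (rather than
re-ranking inside each fold) keeps the selected set stable and cheap but
makes the pooled LOOCV figures mildly optimistic; the held-out test set,
evaluated exactly once after all selection, is the unbiased check.

**Gain contributions.** The final model's per-feature gains, summed by
(motion, family) and normalised to percentages, interpret which motions
and feature types drive each item's score; the table sums to 100.

## Agreement evaluation

* ACC±0 = exact agreement; ACC±1 = |difference| **≤ 1**. (Reading "within
  one" strictly would make ACC±1 collapse onto ACC±0 on an integer scale.)
* Weighted Cohen's kappa over the fixed 4×4 class table. Weights default
  to **linear** — the standard choice for ordinal clinical scales;
  quadratic is selectable, and every report states the scheme. The CI is
  a percentile bootstrap over subjects (2000 resamples by default, seeded;
  replicates whose truth collapses to one class are dropped).
* Spearman's rho with average ranks on ties and the two-sided
  t-approximation p-value.
* Interpretation bands (upper bound inclusive) — kappa: < 0 Poor, ≤ 0.20
  Slight, ≤ 0.40 Fair, ≤ 0.60 Moderate, ≤ 0.80 Substantial, ≤ 1.00 Almost
  Perfect; rho (magnitude): ≤ 0.10 Negligible, ≤ 0.39 Weak, ≤ 0.69
  Moderate, ≤ 0.89 Strong, ≤ 1.00 Very Strong.

Train/test splitting stratifies on the per-subject rigidity + PS total
score; score values are merged upward until every stratum holds ≥ 2
subjects, and a largest-remainder allocation makes the overall test count
exact. Balance tests follow clinical-report conventions: sex by 2×2
chi-square with continuity correction, numeric variables by Welch t-test
(mean ± SD) when Shapiro–Wilk on the pooled values accepts normality at
0.05, otherwise Wilcoxon rank-sum (median[IQR]).

## Item minimization

Greedy backward elimination over whole motions: every round tentatively
drops each remaining motion's full feature block, reruns selection + LOOCV
on each candidate, and keeps the candidate with the best (ACC±0, kappa);
removal ties are broken by dropping the motion with the least total gain
in the current model. The recursion runs down to a single motion, so k
motions always produce k − 1 rounds. The *chosen* set is the smallest one
along the trace with LOOCV ACC±0 ≥ 0.70 (default) — the goal is fewest
motions at acceptable accuracy, i.e. least patient burden, not best
score — with an explicit `no_acceptable_set` flag when no round qualifies.

## Synthetic cohorts

The generator emulates the statistical structure the scoring problem
assumes: a latent per-subject severity s ∈ {0,…,3} that monotonically
degrades movement.

* Cyclic voluntary motions (FT, HM, PSOH, TT, LA): per-cycle amplitude
  `A0·(1 − a·s/3)·exp(−d·(s/3)·cycle)`, frequency `f0·(1 − b·s/3)`, and a
  worse side (random per subject) further attenuated by `(1 − g·s/3)`.
  The coupling is linear in s/3 for interpretability.
* GAIT: antiphase ankle excursion and arm swing shrink with severity;
  AFC: sigmoidal chair rise that slows with severity; POS: sway random
  walk whose step SD grows with severity; PTOH/KTOH: 4–6 Hz fingertip
  tremor that *grows* with severity; FE: action-unit variance shrinks.
* Defaults: 104 subjects; class mix (0.20, 0.35, 0.30, 0.15); 10 s at
  20 fps per motion; effect sizes a = 0.4, b = 0.25, d = 0.3, g = 0.3;
  keypoint noise SD = 3% of each motion's base amplitude; labels =
  latent severity with probability 0.1 of a ±1 deviation (rater
  variability). Base kinematics (e.g. 2 Hz leg agility, 1 Hz gait) sit in
  the physiological range for these tasks.
* `informative_motions` restricts which motions carry severity coupling
  per target (others are generated at severity 0), which makes feature
  selection and minimization behaviour testable.

Everything is emitted in the OpenPose JSON dialect with confidence 1.0 and
read back through the ordinary IO path. What the generator does *not*
emulate: realistic biomechanics and inter-joint coupling, occlusions and
confidence dropouts, camera motion, medication state, or inter-subject
anatomical variability. Synthetic cohorts are therefore *cleaner* than
clinical video: passing tests demonstrate that the pipeline recovers known
structure and that the machinery is correct, not that clinical accuracy
would reach the same level — agreement statistics on simulated cohorts
routinely exceed what heterogeneous patient video can support.

## Orchestration and reproducibility

`run_pipeline` executes simulate/load → preprocess → features → stratified
split + balance → per-target selection/training → gain matrices →
minimization → held-out evaluation, in that order; test-set labels are
first read at the evaluation stage (an audited label store logs every
access into the run summary). One global seed fans out through SHA-256
into named sub-streams (simulate, split, train, bootstrap), all below
2³¹, so stages are independently reproducible and reruns with the same
configuration are byte-identical (artifacts carry the seed and a hash of
the scientific configuration; output paths are excluded from the hash).

## Problem sizes used by the test suite and acceptance script

Chosen to keep a single-CPU run in minutes while leaving the generator at
its default study conditions: cohort-level agreement uses two cohorts of
80 subjects with a {8, 16, 24} feature grid and 60-tree boosters, pooling
LOOCV predictions per target; amplitude/frequency recovery uses 20
single-recording seeds; gain-ranking recovery uses 40 seeds of an
80-subject, 1-informative + 50-noise matrix; minimization recovery uses
10 seeds of 36-subject cohorts over four motions with only gait
informative; the determinism check runs the full pipeline twice on a
20-subject, two-motion configuration. Only compute-scaling knobs (cohort
size, grid, tree count, seed count) differ from the package defaults;
generator effect sizes, noise and label noise are never changed.

## Known limitations

* 2-D image-plane angles conflate out-of-plane rotation with joint
  motion; a frontal camera is assumed.
* The gain ranking is computed once on the training set, so LOOCV curves
  used for choosing k are mildly optimistic (documented above).
* The weighting scheme of the kappa and the CI method are analysis
  choices (linear weights, percentile bootstrap) and are always reported
  alongside the value.
* The channel map is a reconstruction from how these motions are
  performed; a deployment against real pose output may well benefit from
  additional channels (e.g. step-length statistics for gait).
* Hand-only recordings are normalised by wrist-to-knuckle length, which
  varies more across subjects than trunk length.
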