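# rigipose

Touchless scoring of MDS-UPDRS III **rigidity** and **postural stability**
from pose-keypoint time series.

## The problem

The motor examination of Parkinson's disease (MDS-UPDRS part III) contains
two families of items that cannot be assessed over video: rigidity
(item 3.3) requires the examiner to move the patient's limbs and neck
passively, and postural stability (item 3.12) requires a shoulder pull-back
test that is unsafe without a trained examiner. In remote follow-up these
items are simply missing — and without them the motor total score is
invalid.

`rigipose` predicts the four affected ordinal items — upper-extremity
rigidity (Rig-UE), lower-extremity rigidity (Rig-LE), neck rigidity
(Rig-Neck) and postural stability (PS), each scored 0–3 — *indirectly*,
from eleven motions a patient can perform alone in front of an ordinary RGB
camera (finger tapping, hand open/close, pronation–supination, toe tapping,
leg agility, arising from chair, gait, quiet stance, postural and kinetic
hand tremor, facial expression). The package consumes OpenPose-style 2-D
keypoints (25 body points, 21 points per hand, `(x, y, confidence)` per
frame at ~20 fps) and OpenFace-style facial action-unit intensities; it
never runs a pose estimator itself.

## The method

1. **Signals.** Keypoints are cleaned (confidence gating, gap filling),
   normalised by trunk length and flipped to anatomical y-up; each motion
   yields a handful of scalar channels (joint heights, joint-pair
   distances, joint angles, segment orientations). Channels are smoothed
   with a smoothing spline and their peaks and valleys located.
2. **Features, three families.** *Kinematic*: per-cycle amplitude
   (peak − adjacent valley), cycle frequency, rising/falling speed,
   amplitude **decrement** (slope of cycle amplitude vs cycle index, a
   bradykinesia hallmark) and **hesitation** count. *Position* and
   *angle*: time-domain statistics (quantiles, SD, RMS, absolute mean,
   skewness, excess kurtosis) and FFT descriptors (dominant frequency,
   band powers in the voluntary 0.5–3 Hz and tremor 3–10 Hz bands,
   spectral entropy) of position and joint-angle channels. Left/right
   channels are collapsed into mean / max / min / |L−R| features, removing
   worse-side inconsistency.
3. **Models.** One LightGBM multiclass (softmax, 4-class) booster per
   target item. Features are ranked once by total split **gain**; for each
   candidate feature count k, leave-one-out cross-validation measures the
   pooled out-of-fold ACC±0 and weighted kappa of the top-k model, and the
   best (ACC±0, then kappa) wins. The predicted score is the
   argmax-probability class.
4. **Evaluation.** ACC±0 (exact agreement), ACC±1 (within one point),
   linearly weighted Cohen's kappa with a subject-level bootstrap CI, and
   Spearman's rho, each with its conventional interpretation band. Cohorts
   are split by stratified sampling on the rigidity + PS total score, with
   chi-square / Welch-t / rank-sum balance checks.
5. **Item minimization.** Greedy backward elimination over whole motions:
   each round removes the motion whose loss hurts least, and the smallest
   motion set with LOOCV ACC±0 ≥ 0.70 is reported — fewer motions, less
   patient burden.

No clinical recordings ship with the package. A first-class synthetic
cohort generator (`rigipose.simulate`) produces severity-modulated keypoint
recordings in the exact OpenPose dialect — per-cycle amplitude
`A0·(1−a·s/3)·exp(−d·(s/3)·cycle)`, frequency `f0·(1−b·s/3)`, worse-side
attenuation, severity-scaled sway and tremor — with ordinal labels derived
from the latent severity plus rater-style ±1 label noise, so every stage of
the pipeline is testable end to end.

## Worked example

```python
import rigipose as rp
from rigipose.pipeline import preprocess_cohort
from rigipose.modeling import GainSelectedScorer, ModelBundle, gain_contribution_matrix
from rigipose.evaluation import evaluate_predictions, stratified_split

cohort = rp.simulate_cohort(rp.SyntheticCohortConfig(n_subjects=60, seed=42))
clean = preprocess_cohort(cohort.recordings)
features = rp.extract_cohort_features(clean)

split = stratified_split(cohort.labels.sum(axis=1), test_fraction=0.2, seed=42)
train = {s: features[s] for s in split.train_ids}
test = {s: features[s] for s in split.test_ids}

X_train = rp.build_feature_matrix(train, cohort.labels["Rig-LE"], "Rig-LE")
scorer = GainSelectedScorer(grid=(10, 20, 30), n_estimators=100, seed=0)
scorer.fit(X_train.X, X_train.y)
print("selected features:", scorer.selection_.chosen_k)

X_test = rp.build_feature_matrix(test, cohort.labels["Rig-LE"], "Rig-LE")
report = evaluate_predictions(
    X_test.y.to_numpy(), scorer.predict(X_test.X), target="Rig-LE", seed=0
)
print(report.to_text())

bundle = ModelBundle(target="Rig-LE", scorer=scorer, seed=0)
print(gain_contribution_matrix(bundle).round(1))
```

prints

```
selected features: 10
Rig-LE (n=12)
  rho            0.96 (Very Strong), p = 8.047e-07
  weighted kappa 0.91 (0.69-1.00) [Almost Perfect; linear weights]
  ACC±0          0.92
  ACC±1          1.00
      kinematic  position  angle
AFC         0.0       2.4    0.0
GAIT        7.9      21.5   42.0
LA          0.0       0.0    8.1
TT         18.0       0.0    0.0
```

Reading the output: on the 12 held-out synthetic subjects the
lower-extremity rigidity model scores exactly right 92% of the time and
within one point always; the weighted kappa of 0.91 (bootstrap CI
0.69–1.00) is chance-corrected agreement on the 0–3 scale. The gain matrix
attributes most of the model's decisions to gait channels — chiefly angle
and position features — with toe-tapping kinematics second, mirroring how
lower-limb rigidity expresses itself in the generator. (Synthetic cohorts
are cleaner than clinical video, so agreement is higher than one should
expect on real patients.)

The estimators follow the scikit-learn protocol (`fit` / `predict` /
`predict_proba` / `get_params`), so they compose with sklearn model
selection. A CLI mirrors the stages
(`rigipose simulate | extract-features | split | train | predict |
evaluate | minimize | run-all`); `run-all` drives the whole pipeline from
one YAML file and writes every artifact (split, balance table, per-target
model bundle, report, gain matrix, minimization trace) with the seed and a
configuration hash, byte-reproducibly.

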