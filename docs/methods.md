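# Methods

## Problem and model

`cawarn` predicts whether an ICU stay will experience a cardiac arrest
(CA) in the hour following a 12- or 24-hour observation window. The input
is irregularly sampled multivariate vital signs — heart rate (HR),
systolic/diastolic/mean blood pressure (SBP, DBP, MBP), temperature
(TEMP), respiratory rate (RR) and oxygen saturation (SPO2) — plus two
derived hourly early-warning subscores (EWS) for TEMP and SPO2. The
classifier is a gradient-boosted decision-tree ensemble trained with
cost-sensitive per-sample weights, operating on a fixed-length feature
vector built from multiresolution segment statistics and
cosine-similarity temporal-pattern features.

## Preprocessing

1. **Outlier removal.** Observations outside per-channel acceptable
   ranges (HR 20–300 bpm, SBP 30–300, DBP 10–200, MBP 20–250 mmHg, TEMP
   30–43 °C, RR 4–60 /min, SPO2 50–100 %) are dropped. The intervals are
   closed and configurable.
2. **Bucketization.** Observations are averaged within half-open 1-hour
   buckets `[t, t+1)`; empty buckets are marked missing.
3. **Imputation.** Missing buckets take the nearest *later* observed
   value in the channel (backward fill), then trailing gaps take the
   nearest earlier value (forward fill). This is idempotent and complete
   whenever each channel has at least one observation; a fully empty
   channel is an error by default, with an optional population-mean
   fallback.
4. **EWS subscores.** Hourly 0–3 band scores from imputed TEMP and SPO2:
   TEMP ≤35.0→3, (35.0, 36.0]→1, (36.0, 38.0]→0, (38.0, 39.0]→1, >39.0→2;
   SPO2 ≤91→3, (91, 93]→2, (93, 95]→1, >95→0. Classic early-warning band
   tables differ between hospitals; these defaults span the full 0–3
   range on both sides of a normal band and are configurable.
5. **Normalization.** Per-channel z-scoring, with mean/SD estimated on
   *training stays only* inside each cross-validation fold and reused
   verbatim at prediction time. Normalizing before splitting would leak
   test-set statistics into training, so the package deliberately fits the
   normalizer per training fold. Zero-SD channels map to 0. EWS channels
   are z-scored like the rest.

## Features

All features are computed on the z-scored 9-channel grid. With window
T=24 and resolutions {4, 6, 12, 24} (resolutions exceeding T are skipped,
so T=12 effectively uses {4, 6, 12}):

- **Segment statistics** (585 at T=24): the grid is cut into consecutive
  non-overlapping segments per resolution (6+4+2+1 = 13 segments at
  T=24); each segment × channel summarized as mean, median, min, max and
  population SD (ddof=0, so length-1 segments are well defined). The
  segments are non-overlapping by design: a fixed feature-vector length
  requires stride = segment length.
- **Cosine-similarity features.** Time-level T×T and channel-level C×C
  cosine-similarity matrices (zero-norm vectors get similarity 0; the
  diagonal is exactly 1 for nonzero vectors). Each row is reduced to the
  mean and SD of its off-diagonal entries — self-similarity is constant 1
  and would only dilute the aggregates. The time-level profiles are then
  run through the same segmentation machinery (130 features at T=24); the
  channel-level aggregates are emitted directly (2×9 = 18).
- **Weighted-matrix features** (90): the grid rescaled elementwise by the
  time-level profile (`W_time[t,c] = grid[t,c]·m_t[t]`) and by the
  channel-level profile (`W_chan[t,c] = grid[t,c]·m_c[c]`), each
  summarized per channel over the full window with the five statistics.
  This couples raw trajectories with how typical each hour (or channel)
  is of the rest of the window; the exact elementwise form is this
  package's construction, isolated in one function so alternatives can be
  swapped.

Total: 823 features at T=24, 438 at T=12. Names follow a fixed grammar
(`RR_18-24h_median`, `Cos_time_mean_0-4h_sd`, `Cos_chan_mean_HR`,
`W_time_HR_max`) so attribution outputs stay readable, and the
hour spans can be parsed back out for temporal-importance summaries.

## Classifier and operating point

LightGBM binary ensemble with per-sample weight 100 on CA stays,
learning rate 0.04, validation-AUROC early stopping with 500-round
patience, and reset to the best iteration (applied whether or not the
patience window triggers). Maximum rounds default to 500: at the cohort
sizes this package targets, the 0.04 learning rate converges well within
that budget. Tree-shape parameters stay at library defaults except
`max_bin`, lowered to 63: with z-scored inputs the finer default
histogram granularity changes nothing measurable while tripling training
time. Training is single-threaded and deterministic given the seed; that
is the documented reproducibility contract.

The decision threshold is chosen on the early-stopping validation split
by maximizing the Youden J statistic (sensitivity + specificity − 1) over
observed score values, predicting positive at score ≥ threshold; ties in
J break toward the lower threshold, i.e. higher sensitivity, and a score
exactly at the threshold is classified positive.

## Evaluation protocol

Stratified 10-fold cross-validation at stay level (stratification keeps
folds non-degenerate at ~4% prevalence). Inside each training fold a
stratified 80/20 split supplies the early-stopping validation set and the
Youden threshold; the spec's outer-CV and train/validation/test protocols
are nested this way. Reported metrics: precision, sensitivity,
specificity, F1 (at each fold's own threshold), AUROC (Mann-Whitney with
0.5 credit for ties), AUPRC (average-precision convention) and the Brier
score, as per-fold mean±SD plus 95% percentile bootstrap CIs (1000
stratified resamples of the pooled out-of-fold scores).

The lead-time curve re-anchors the observation window to end L hours
before the event horizon (L = 1…6), re-runs the entire pipeline per lead
with identical fold assignment (paired folds), and records the test
AUROC. Retraining per lead is the default; stays whose re-anchored
window loses a whole channel are excluded from every lead so folds stay
comparable.

## Synthetic cohorts

Real early-warning cohorts live in credentialed clinical databases, so
the generator emulates their structure:

- **Baselines**: per-channel means/SDs default to published ICU
  heart-failure cohort statistics for non-arrest stays (HR 87.11 (17.22)
  bpm, SBP 117.81 (21.72), DBP 59.23 (14.28), MBP 75.59 (14.88) mmHg,
  TEMP 36.93 (0.71) °C, RR 21.05 (5.79) /min, SPO2 96.98 (3.11) %);
  default prevalence 82/1981 ≈ 4.1% matches that cohort design.
- **Trajectories**: stationary Gaussian AR(1) per channel with lag-1
  autocorrelation 0.8 at 1 h, a shared innovation factor giving
  cross-channel correlation 0.3 — smooth, cheap, and structured enough
  for the similarity features to have something to detect.
- **Sampling**: per stay-hour-channel, Poisson(1.0) observations placed
  uniformly in the hour; whole buckets dropped with probability 0.1; at
  least one observation per stay-channel is always kept so imputation is
  defined. Values are unbounded Gaussians — tails beyond physiological
  ranges (e.g. SPO2 > 100) are left for the outlier filter to exercise.
- **Destabilization** (CA stays only): from a configurable onset before
  the end of the record, a linear drift of `effect_size` baseline-SDs —
  HR and RR up, SBP and SPO2 down — plus variance inflation
  ×(1 + effect_size/2), and optionally loss of the shared cross-channel
  factor. This mimics the clinical observation that vital signs become
  unstable and decorrelated before arrest; the precise generative form is
  an artifact decision (real pre-arrest dynamics are unknown), so passing
  signal-recovery tests demonstrates that the pipeline detects *this
  kind* of destabilization, not that it would achieve the same
  discrimination on real patients.

What the generator does not emulate: interventions and medication
effects, measurement-device artifacts, multi-event stays, long-range
nonstationarity, and realistic missingness mechanisms (missingness here
is completely at random, whereas clinical sampling intensifies when staff
are worried).

## Numerical choices and degenerate inputs

- Cosine similarity of a zero-norm vector is 0 by convention; matrices
  are symmetrized and clipped to [−1, 1] against floating-point drift.
- SD=0 channels z-score to 0; segment SDs use the population convention.
- Undefined confusion ratios (zero denominators) are reported as 0 and
  flagged.
- Bootstrap resampling is stratified by class so every replicate keeps
  both classes.
- All randomness flows through named integer seeds
  (simulation/folds/bootstrap/model); fixed seeds give bit-identical
  cohorts and reports.

## Problem sizes

The bundled evaluation scripts and acceptance checks use 2000-stay
cohorts (≈83 arrests at default prevalence), 10-fold CV, 1000 bootstrap
iterations, and lead times up to 6 h — the package's standard desk-scale
study conditions.

## Known limitations

- The feature set is fixed-length by construction; it cannot represent
  windows longer than the configured T without re-deriving names.
- Lead-time evaluation needs records extending `T + max_lead − 1` hours;
  shorter stays are excluded rather than padded.
- The single-tree baseline shares the boosting objective (it is a
  one-iteration boosted model at the configured learning rate), not a
  CART tree fit to purity.
- Probabilities are raw ensemble outputs; no recalibration is applied, so
  the Brier score reflects the cost-weighted training distortion.
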