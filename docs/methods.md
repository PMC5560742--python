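# Methods

This note documents the models, parameter choices and numerical conventions
behind `wmreplay`, and what its synthetic-data tests do and do not show
about real recordings.

## Task and data model

Each trial of the simulated experiment presents three stimuli — one from
each of the categories F (face), B (natural item), C (manufactured object),
each from one of three perspectives — for 500 ms with 500 ms gaps, followed
by a 5000 ms retention period and two memory probes (same/different detail
judgment, then serial-order judgment).  The complete design crosses 6
category orders with 3 perspectives per position: 162 unique trials in 6
runs of 27, each seen once, with probe position balanced over 1..3 and the
correct detail answer "same" on exactly half the trials.

Sensor data are trials x channels x samples arrays in tesla (274 channels,
600 Hz by default), carried in a plain array container with a millisecond
time axis and per-epoch event metadata, serialized to HDF5.  No vendor MEG
formats are read: the analysis is format-agnostic and no public recordings
exist for this paradigm.

## Synthetic-data generator

The generator is not a fixture but the package's ground-truth model; every
analysis stage is validated by recovering what it injected.

**Encoding.**  Each stimulus epoch spans −100..500 ms and contains
(i) white Gaussian channel noise of SD `noise_sd_t` = 1e-13 T,
(ii) a category-specific spatial pattern (unit-norm channel vector, pairwise
|cos| ≤ 0.3) under a Gaussian temporal kernel peaking at 170 ms (SD 40 ms),
gated to t ≥ 0, with peak amplitude `snr_encoding` x noise SD, and
(iii) an attention component: a fixed (subject-independent) unit-norm
topography under a kernel peaking at 125 ms (SD 25 ms).  One stimulus per
trial is designated *to-be-predominantly-maintained* (PM), uniformly over
the three positions; its attention component is multiplied by
`attention_gain_pm` = 0.6 — the dominant maintenance item is the weakly
attended one.  The attention topography is fixed across subjects because
the early visual-attention response has a consistent sensor distribution in
a group; this is what makes a group-level PM/non-PM evoked contrast
meaningful.  Epochs include the closing sample at +500 ms so the final
20 ms decoding bin has its full 13 samples.

`snr_encoding` = 1.0 was calibrated once so that the full-scale pipeline
(274 channels, 162 trials) reproduces the encoding-decodability regime the
analysis assumes: peak mean cross-validated accuracy ≈ 78% at the 170 ms
bin.  It was then frozen.

**Retention and ITI.**  A first-order Markov chain over abstract states
(S1, S2, S3, N), one step per 20 ms bin, drives the retention window.  Per
trial, S1 maps to the PM category and S2/S3 to the other two categories in
sequence order; with `position_coding=True` the states map to sequence
positions instead, which is the representation in which forward (1-2-3) and
backward (3-2-1) replay are defined and injected.  The default generator

| from\to | S1 | S2 | S3 | N |
|---|---|---|---|---|
| S1 | 0.972 | 0.002 | 0.002 | 0.024 |
| S2 | 0.028 | 0.900 | 0.002 | 0.070 |
| S3 | 0.028 | 0.002 | 0.900 | 0.070 |
| N  | 0.087 | 0.004 | 0.004 | 0.905 |

was designed against its stationary distribution (0.73, 0.02, 0.02, 0.22):
the sticky PM state gives roughly half the trials a dominant-category run
longer than 1100 ms; non-PM categories are entered rarely and replay
briefly; and the ~22% null occupancy matches the fraction of retention bins
the d* rule rejects, so the rejection threshold separates replay from
no-replay bins instead of truncating replay runs.  Category-to-category
transitions are symmetric: the default generator carries no sequence
direction, matching the null the directionality test is calibrated on.
The ITI uses a separate, mostly-null generator (null self-transition 0.97)
and a null-dominated initial distribution: fixation has no mnemonic
content.

Bins labeled F/B/C add the matching category pattern (constant within the
bin, amplitude `snr_replay` x noise SD) to the noise; N bins are noise
only.  `snr_replay` = 6 gives a sharp separation between the decision-margin
distributions of replay and no-replay bins, the regime in which a single
retention-derived threshold also rejects the large majority of ITI bins.
Both analysis windows carry one extra trailing sample so their last bins
are complete.

**Behavior.**  Detail-test hits are Bernoulli with
logit = `behavior_intercept` (1.1) + `behavior_slope` (5e-4 per ms) x
longest consecutive replay of the probed category; order responses have a
replay-independent accuracy of 0.75; response times are lognormal
(median 900 ms, sigma 0.3) with a replay coefficient of −5e-5 per ms on the
log scale for the detail test.  Saturation behaves correctly (an extreme
intercept gives a 100% hit rate regardless of replay).

**What the generator does not emulate.**  Noise is white per channel: no
1/f spectrum, no inter-channel covariance, no physiological artifacts
beyond optional amplitude outliers for the rejection test, no head
geometry (the ERF analysis uses a synthetic planar sensor layout for
channel adjacency).  Passing tests therefore demonstrate that the
*estimators and tests* behave correctly under the stated model, not that
real recordings satisfy that model; on real data, effect sizes and the
margin distributions will differ, and the reliability-derived rejection
fraction is the only part of the thresholding that transfers by
construction.

## Analysis conventions

- **Windows.**  Cropping is half-open [start, end).  The retention analysis
  window is [1000, 4000) ms after the last stimulus offset (the first
  second is excluded as offset-evoked activity); the control window is the
  3000 ms before the first stimulus onset.  Both contain 150 bins of 20 ms.
  A 151-bin reading of these windows exists (fencepost counting of bin
  edges); the 3000/20 = 150 definition is used throughout and noted in run
  reports.
- **Bins.**  Decoding bins are indexed by center (−10, 10, ..., 490 during
  encoding) and span center ±10 ms inclusive: 13 samples at 600 Hz.
  Features are channel-major flattenings (13 x 274 = 3562 features).
- **Classifier.**  Linear SVM with C = 1 (the implementation default;
  exposed in the API).  Classes are balanced by seeded downsampling to the
  smallest class before cross-validation.  Feature screening (two-tailed
  two-sample t test, keep p < 0.05) and z-scoring are learned inside each
  training fold only; if no feature survives the screen, the single
  smallest-p feature is kept.  Decision values are signed so a positive
  margin favors the pair's first category in the canonical order F < B < C.
  The classifiers applied to the delay are refit on all encoding trials at
  the selected bin.
- **Label rule.**  A delay bin's label is the category favored by the
  pairwise decision of largest |margin|, with that |margin| as the
  confidence d.  Exact ties resolve to the earliest category in F < B < C;
  an all-zero bin decodes as F with d = 0 and is rejected by any positive
  threshold.  Margins are not recalibrated across the three classifiers —
  they share one training pipeline.
- **Rejection threshold.**  d* is the lower empirical quantile (an order
  statistic, no interpolation) of the pooled retention-period distances at
  probability 1 − reliability, where reliability defaults to the mean
  cross-validated accuracy at the selected bin (override available).  On
  the defining set the rejected fraction equals the target to within one
  rank position — with 10,000 bins and reliability 0.78, exactly 22% are
  rejected.  The threshold is computed per subject over all retention bins
  pooled across trials (per-trial thresholds are unstable), and the same
  threshold is applied to the ITI.
- **Replay epochs.**  Maximal runs of identical non-null labels; lengths
  live in bin units internally (ms = bins x 20 at presentation).  Length
  histograms use the ranges 20-140, 160-400, 420-1100 and >1100-3000 ms;
  the top range begins at 1120 ms because lengths are multiples of 20 ms
  and everything above 1100 ms is "long replay" by the grouping rule.
- **Transition matrices.**  Transitions are counted between consecutive
  bins within a trial's window only — never across trials, which would
  fabricate transitions across seconds-long gaps.  N is a full Markov state
  (transitions to and from N are counted); the forward/backward products
  use only the stimulus states.  Rows never visited have undefined (NaN)
  probabilities and exclude the subject from affected comparisons, with the
  exclusion logged.
- **Rank-sum tests.**  Two-sided Wilcoxon rank-sum; exact enumeration for
  group sizes ≤ 10 per side without ties, tie-corrected normal
  approximation otherwise.  Rank-sum is used for both the epoch-histogram
  and the transition-probability comparisons (the test for the former is a
  package choice, named in reports).
- **Predominance.**  The PM category of a trial is the one with the most
  decoded retention bins; ties break by longest single epoch, then earliest
  occurrence.  A longest-single-epoch rule is available behind
  `predominance_rule="longest"`; reports name the rule in effect.
- **Familywise error.**  All multiple-comparison control is by cluster
  permutation: sign-flip max-cluster-mass over the 1-D accuracy curve
  (cluster-forming one-sided t at p < 0.05, 5000 permutations by default),
  and spatio-temporal cluster permutation over channels x time for the
  PM/non-PM evoked contrast (within-subject sign flip of the condition
  difference, 2000 permutations, k-nearest-neighbor channel adjacency on
  the sensor layout).  Cluster permutation was chosen over parametric
  random-field correction because it gives exact control under
  exchangeability without a smoothness model; every report names the
  method.
- **Behavior models.**  The mixed model is `outcome ~ replay_ms` with a
  subject random intercept, fit by REML; binary accuracy is modeled on the
  0/1 scale (linear), with a pooled logistic variant behind a flag.  A
  singular or non-convergent fit falls back to pooled ordinary regression
  with a warning and is flagged in the output.  Response-time analyses use
  correct trials only by default (configurable).  The replay grouping is
  none / short (20..1100 ms) / long (> 1100 ms, strict) on the probe
  category's longest retention epoch.
- **ERF contrast.**  Per subject, the PM and non-PM averages come from
  disjoint epoch sets; trials whose retention period decoded to no PM
  category are excluded from both.  The group statistic is the squared
  one-sample t of the per-subject difference maps (an F with one numerator
  degree of freedom); sensor-level only — no source localization.

## Determinism

Every source of randomness derives from explicit seeds: the simulation
draws from tagged substreams of `SimulationParams.seed`, per-subject seeds
derive from the run seed via a seed sequence, and fold assignment,
permutation tests and downsampling all take seeds.  Two runs with equal
config and seed produce byte-identical result tables; the run manifest
records SHA-256 checksums and the config hash, and artifacts from different
configs refuse to mix.

## Problem sizes

Unit and calibration tests run at reduced scale — 16-24 channels, 15-54
trials, 8-14 simulated subjects, 100-500 permutations — chosen as the
smallest sizes at which the tested property is identified (the decoding
geometry is channel-count-free; only effect sizes change).  The full-scale
defaults (274 channels, 162 trials, 14 subjects, 5000/2000 permutations)
are exercised in the worked examples and available through
`PipelineConfig`.

## Known limitations

- The label rule and d* threshold assume the three pairwise margins are
  commensurable; no cross-classifier calibration is applied.
- The linear treatment of binary accuracy in the mixed model follows the
  analysis being re-implemented; the logistic variant is pooled (no
  random-intercept logistic fit).
- The repeated-measures ANOVA on PM proportions has structurally dependent
  cells (proportions sum to 1 within subject); it is reported as in the
  original analysis design, and degenerate (zero-variance) inputs return a
  null result rather than an error.
- Directionality products assume independent per-step replay probabilities;
  they are descriptive statistics, not a fitted sequence model.
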