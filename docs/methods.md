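# Methods

`momdecode` implements an end-to-end analysis of vigilance decrements in a
multiple-object monitoring (MOM) setting: a task simulator, multivariate
decoding of stimulus information from multi-sensor epochs, RDM-based
informational connectivity, a single-trial behavioural-error predictor,
and JZS Bayes-factor statistics.  This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
generator does and does not emulate.

## Task model

A MOM session consists of blocks (default 110 s) of moving dots (default
64 per block, 32 per colour) travelling from two screen corners toward a
central object.  Cued-colour ("attended") dots may be targets that fail to
auto-deflect at the deflection point and must be deflected by a button
press before collision.  Target frequency defines the conditions: Active
blocks contain 16 targets among the 32 cued dots (50%), Monitoring blocks
2 (~6.2%).  The default schedule runs 15 blocks per condition — 1920 dots
in total.  Timing landmarks are drawn per dot: onset-to-deflection
1226 ± 10 ms, deflection-to-collision 410 ± 10 ms, inter-onset interval
1660 ± 890 ms.

Onset scheduling draws inter-onset intervals from a truncated normal
(minimum 100 ms) and rescales onsets linearly so all dots start — and
nominally finish moving — inside the block.  Only the ISI mean ± SD is a
design quantity; the truncation/rescale rule is this package's choice for
making the draws fit the block, and a configuration whose dot count cannot
fit the block at the minimum ISI raises a scheduling error.  Trajectory
geometry is never rendered: the analyses consume only timing landmarks and
the ordinal distance bin, so the simulator emits times, not pixels.
Practice blocks are configuration bookkeeping only; they are excluded from
every analysis and therefore not materialised.

## Behaviour model

Miss probability in block *b* (1-based within condition):

* Active: `max(active_floor, base_miss_prob − active_learning_slope·(b−1))`
* Monitoring: `clip(base_miss_prob + monitoring_extra_miss + vigilance_slope·(b−1), 0, 1)`

Defaults (`base_miss_prob` 0.29, `monitoring_extra_miss` 0.11,
`active_learning_slope` 0.03, `active_floor` 0.17, `vigilance_slope`
0.026) reproduce the canonical vigilance-decrement pattern: block-1 miss
rates near 29% (Active) and 40% (Monitoring), an Active plateau near 17%
after five blocks, Monitoring misses climbing toward ~76% by block 15.  A
single base-plus-slope parameterisation cannot produce the fall-then-
plateau Active curve, hence the explicit floor and the separate Monitoring
offset.  Hit RTs are truncated normal within the deflection-to-collision
window (mean 280 ms, SD 60 ms), drifting −3 ms/block under Active and
+4 ms/block under Monitoring.  False alarms occur at 3.5% per non-target
dot, split between early presses, presses to auto-deflecting events, and
wrong-colour presses; simulated presses are generated per dot, so the
"attribute the press to the dot nearest the centre" rule is exact by
construction.

## Sensor model

Epochs span −100..3000 ms around dot onset at 1000 Hz (default 160
sensors).  The signal is

```
gain(colour) · [ a_trial · direction_amp · p_dir
               + dist_scale · distance_amp · p_dist(bin(t)) ] · env(t) + noise
```

* `env(t)`: box-car from 100 ms post-onset to the deflection point with
  20-ms half-cosine ramps — decoding therefore becomes possible from
  roughly 100 ms after onset.
* `p_dir`: a fixed random unit vector; its sign codes left vs right.
* `p_dist(d)`: 15 unit vectors tracing a quarter great-circle between two
  random orthonormal vectors, so neighbouring distance bins have similar
  patterns and separability grows with ordinal distance — the property
  that makes the RDM ordinal.  `frontal_distance_gain` rescales the
  distance patterns on the frontal sensor group (0 localises distance
  information to occipital sensors).
* `gain` = `attention_gain` (default 1.6) on cued-colour trials, 1
  otherwise.
* On miss trials `dist_scale` = `miss_attenuation` (default 0.6) and the
  per-trial direction amplitude jitter SD (default 0.25) is multiplied by
  `miss_direction_noise_inflation` (default 2.5): misses carry weaker
  distance information and noisier direction information.
* `noise_sd` 1.0 per sensor-sample, i.i.d. Gaussian.

Amplitudes (`direction_amp` 0.4, `distance_amp` 0.25) were calibrated once
so that, at the default 160-sensor model after 200-Hz downsampling,
single-trial mean distance-decoding accuracies centre near 0.60 on correct
and 0.56 on miss trials with a correct-vs-miss Cohen's d around 0.5, the
regime the analyses are designed for.

Epochs are generated independently per dot even though the schedule
overlaps dots on screen; the decoding pipeline analyses per-dot epochs the
same way.  The generator emulates information *content* and its modulation
by attention and outcome.  It does not emulate real M/EEG spatial
covariance, 1/f spectra, artefacts, eye movements, or inter-subject
variability in sensor geometry — passing tests therefore demonstrate that
the pipeline recovers the effects its inputs contain, not that real
recordings contain them.

## Preprocessing

* **Downsampling**: FIR anti-alias filter + decimation
  (`scipy.signal.decimate`, zero-phase).  The first sample is retained, so
  a −100..3000 ms epoch at 1000 Hz (3101 samples) yields 621 samples at
  200 Hz.  Filter edge transients span ~50 ms at each epoch edge.
* **Distance binning**: each trial's onset-to-deflection span is divided
  into 15 equal time windows (constant dot speed makes equal time equal
  distance; bin width ≈ 82 ms at the default timing).  Each retained
  sample joins the temporally closest bin centre — for equal windows this
  is the containing window, and a sample exactly on a boundary joins the
  later (nearer-object) bin.  Bins are indexed by distance: 15 = dot just
  appeared, 1 = nearest the object.  Within each bin, samples are
  decimated uniformly to `samples_per_bin` (default 5).  At 200 Hz an
  ~82-ms window holds ~16 samples; the 4-5-samples-per-bin feature size is
  the analysis convention this package follows, with the within-bin
  decimation exposing the full-resolution option (`samples_per_bin=16`).
  Feature vectors are flattened sensor-major, time-minor.
* **Direction pooling**: trials from both approach directions share
  distance-class labels, so distance decoding cannot exploit the direction
  signal; pooling is idempotent and the direction label is retained.
* **Trial equalization**: seeded subsampling of every condition cell to
  the global minimum count, so condition contrasts cannot reflect trial
  numbers.

## Decoding

The classifier is closed-form two-class LDA: pooled within-class
covariance shrunk toward the scaled identity, `S_reg = (1−λ)S +
λ(tr S/p)I`, weight vector `w = S_reg⁻¹(m₁−m₀)`, cut at the projected
midpoint.  A discriminant of exactly zero goes to the first class (fixed,
tested tie rule).  The default is a fixed λ = 0.2: with 160-sensor ×
multi-sample features and ~100 training trials regularisation is
mandatory, and a fixed λ keeps the regularisation identical across folds,
time points, and condition cells (and is markedly cheaper over the
~10⁵-10⁶ covariance fits of a full run).  Analytic Ledoit-Wolf shrinkage
remains available (`shrinkage="ledoit-wolf"`).

* **Direction decoding**: left vs right at every 5-ms step (one sample at
  200 Hz), features = all sensors at that sample.  10-fold
  cross-validation with folds assigned to whole trials; within each fold's
  training set the two classes are equalized by seeded subsampling; fold
  accuracies are averaged with equal weight.
* **Distance decoding**: all 105 unordered pairs of the 15 distances.
  Every trial contributes one sample per distance, so pair classes are
  balanced by construction and the trial-grouped folds guarantee that a
  trial's samples never straddle train and test.  Per-trial 0/1
  correctness is retained per pair, at both of the pair's distances, for
  the downstream error analyses.  Per-distance accuracy is the mean of a
  distance's 14 pairings.

## Informational connectivity

Spearman rank correlation between the 105 lower-triangle entries of the
frontal-group and occipital-group RDMs.  Default sensor groups are the
first and last quartiles of the sensor index range (real montages would
supply explicit sets).  Rank correlation makes the measure invariant to
any strictly increasing transform of either RDM, hence insensitive to
overall decoding level.  Condition-wise connectivity equalizes trials
across the eight attention × frequency × time-on-task cells; the
correct-vs-miss contrast subsamples correct trials to the miss count and
averages over 100 seeded repetitions (configurable).  A constant RDM
triangle has no defined rank correlation; such cells are flagged NaN with
a warning and excluded from group statistics.

## Error analyses and outcome prediction

Only attended trials enter (unattended dots have no behavioural outcome),
and only pre-deflection data (the visual input differs between outcomes
after the deflection point); distance bins end at deflection by
construction.

* **Generalization**: classifiers train exclusively on correct trials and
  are tested on held-out correct folds and on all miss trials.  The fold
  count is `round(n_correct / n_miss)` clamped to ≥ 2, so each held-out
  correct fold approximately matches the miss count and the comparison is
  count-balanced.
* **Single-trial distributions**: per-trial mean classifier correctness,
  summarised per outcome and compared with pooled-SD Cohen's d (flagged
  undefined below 2 trials per outcome).
* **Accumulated accuracy**: for a test trial at distance *d*, the mean of
  the 0/1 correctness of every pair classifier involving any distance
  ≥ *d*, each evaluated on the trial's sample at the pair's farther
  distance (the distance at which that classifier joined the
  accumulation).  The count obeys `N(d) = C(15,2) − C(d−1,2)`: 14 at
  d = 15, 27 at 14, …, 105 at 1.
* **Threshold rule**: correct trials split ~80/10/10 into train /
  validation / test; a test trial is labelled *miss* at distance *d* when
  its accumulated accuracy falls strictly below `mean_val(d) − m ·
  sd_val(d)` (a trial exactly on the boundary counts as correct).
  Below-boundary ⇒ miss is the direction consistent with stronger
  information coding on correct trials.  Validation statistics are
  computed per distance (the boundary is applied at a given distance); a
  pooled variant would be a one-line change.  `m` sweeps 0.1..4.0 in
  steps of 0.1.
* **Accuracy**: balanced accuracy (mean of per-class accuracies), the
  deterministic equivalent of equalizing correct and miss test counts;
  chance is 0.5 regardless of class imbalance.
* **LOSO transfer**: each subject's best multiple is the argmax of
  distance-averaged accuracy (exact ties averaged); the held-out subject
  receives the mean of the other subjects' best multiples, avoiding
  circularity.  Miss trials and test-correct trials never enter training
  or validation statistics (audited by trial ID in the tests).

The same generalization runs with false alarms (all three types pooled)
in place of misses via `miss_outcomes`.

## Bayes factors

* **JZS t-test**: Cauchy(0, r) prior on the standardized effect
  (default r = √2/2), computed by one-dimensional quadrature over the
  variance-mixing parameter g (inverse-gamma(1/2, r²/2)); one-sample,
  paired, and pooled-variance two-sample forms.  The BF depends on |t|
  only, is invariant to rescaling the data, and is cross-checked against
  pingouin's implementation in the tests.  A "data-driven" prior scale is
  sometimes used in this literature but is not reproducible from verbal
  descriptions; the fixed default scale is exposed as `r`.
* **Shuffled-null BF**: subject accuracies against an empirical null of
  1000 seeded label-shuffled accuracies, via the two-sample JZS machinery.
* **BF ANOVA**: balanced within-subject 2×2×2 designs.  Sum-to-zero effect
  columns carry g-priors (scale 0.5 on fixed-effect blocks, 1.0 on the
  subject random block); for a main effect, the full model holds all main
  effects and the restricted model drops the tested factor; for an
  interaction the full model adds it to the main effects.  Marginal
  likelihoods integrate over g by seeded Monte Carlo (default 2000 draws),
  so identical seeds reproduce identical BFs.  No multiple-comparison
  adjustment is applied across time points or distances; BFs are reported
  pointwise.
* **Categories**: BF10 > 10 / > 3 strong / moderate evidence for the
  alternative; < 1/10 and < 1/3 the mirror for the null; in between,
  insufficient.

## Seeds and determinism

All randomness flows through `numpy` Generators seeded by
`derive_seed(master, *tokens)` — a SHA-256 hash of the master seed and
context tokens (stage, subject, repetition), kept below 2³¹.  Identical
configuration + master seed reproduce schedules, outcomes, epochs, fold
assignments, subsamples, and Monte-Carlo integrations bit-identically;
the pipeline writes a manifest with SHA-256 hashes of every artefact.

## Problem sizes

Full-scale runs (21 subjects × 1920 trials × 160 sensors) are supported
but long; the package's own test and verification runs use scaled
sessions that preserve every structural property of the design:

* unit tests: 16 dots per 40-s block, 6 blocks per condition, 16 sensors;
* parameter-recovery cohorts: 21 subjects, 24 dots per 60-s block (12 per
  colour, 6 Active / 2 Monitoring targets), 10 blocks per condition, 16
  sensors, 3 samples per bin, epochs generated at 1000 Hz and downsampled
  to 200 Hz;
* the shuffled-label chance-level check: one subject at the default
  160-sensor model with one block per condition (128 trials) and 100
  label shuffles — the permutation chance level does not depend on the
  trial count.

Behaviour-only recovery uses the full default schedule (it is cheap).  The
Monitoring condition contributes only ~10 target outcomes per subject and
time-on-task cell, so any single simulated cohort has a non-trivial
false-positive rate in null checks; the recovery suite therefore evaluates
the behavioural interaction as the median BF over three independent
cohorts.

## Known limitations

* The generator's noise is white and spatially uncorrelated; absolute
  decoding accuracies are not comparable to real recordings, only the
  structure of effects is.
* The BF ANOVA's Monte-Carlo integration has sampling error (small at the
  default 2000 draws and fixed by the seed, but present); it is validated
  behaviourally rather than against an external closed form.
* The deposited-data reader maps MAT-format containers with a documented
  key layout; it is schema-tolerant about key names but does not guess
  arbitrary structures — unknown layouts raise an error listing the keys
  found.
* Informational connectivity is computed over the whole trial (one RDM
  per cell), not time-resolved, and no directed measures are provided.
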