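# Methods

This note documents the models, numerical choices and known limitations
of the `gaitfatigue` pipeline: from raw lower-back triaxial
accelerometry (100 Hz, ±8 g) and momentary fatigue diaries (physical and
mental fatigue, Likert 0–6, up to four entries/day) to walking bouts,
gait events, pooled features, mixed-model associations and low/high
fatigue classification.

## Walking-bout detection

The recording is lowpass filtered (2nd-order Butterworth, 17 Hz) and cut
into non-overlapping 0.1-s windows. A window counts as *upright and
moving* iff the summed per-axis SDs reach 0.05 g **and** the mean
vertical acceleration is at most −0.77 g. Runs of active windows closer
than 20 windows (2 s) are merged left-to-right; merged runs shorter than
20 windows are dropped. Gaps of exactly 20 windows are not merged and
bouts of exactly 20 windows are retained (both rules are strict
"fewer than 20" comparisons).

Two deliberate choices:

* **Mean normalisation vs the upright test.** Removing the signal mean
  before windowing would make the −0.77 g threshold unsatisfiable, so
  the SD condition is evaluated on the filtered signal (SDs are
  shift-invariant) and the mean condition on the filtered,
  gravity-retaining signal. This preserves the physical meaning of the
  upright test.
* **Zero-phase filtering** (forward–backward Butterworth) everywhere, so
  thresholds and event times carry no filter lag.

Windows overlapping missing samples are inactive by definition, and
bouts never span a gap; the walking/non-walking partition of valid time
is exact up to one 0.1-s window per gap edge (partial windows at gap
boundaries belong to neither class).

Orientation is corrected automatically: any day whose vertical-axis mean
is positive has all three axes sign-flipped (an upside-down sensor
inverts VV and AP together). The rule is idempotent and replaces manual
inspection for reproducibility.

## Gait events

Within each walking bout the vertical axis is detrended, mean
normalised, lowpass filtered (4th-order Butterworth, 20 Hz), integrated
(cumulative trapezoid) and differentiated with a Gaussian
first-derivative CWT — a smoothed differentiator. Initial contacts (IC)
are local minima of that signal, final contacts (FC) local maxima of a
further CWT differentiation. Minima are kept when their depth (relative
to the signal mean) reaches 0.4× the mean candidate depth; maxima need
0.25× the mean candidate height. A floor of 1e-8 discards
float-precision dust on flat signals.

The CWT scale defaults to `sampling_rate / 10` samples (step-frequency
scale) and is exposed in the API; no published scale exists for this
chain.

**FC indexing.** The FC array is aligned so that `fc[i+1]` is the first
detected FC inside `(IC_i, IC_{i+1})`; stance time of step *i* is then
`fc[i+1] − IC_i`, stride `IC_{i+2} − IC_i`, swing their difference. The
alternative alignment (first FC *after* `IC_{i+1}`) was rejected: under
this detection chain it yields swing times around 0.15 s for any
realisable waveform, which the step-outlier mask (swing < 0.23 s) would
then delete wholesale.

Exclusions run in this order: bouts with fewer than three detected steps
are removed; the first three and last five steps of each bout are masked
(gait initiation/termination); steps with step time outside
(0.25, 1.25) s, step length outside (0.23, 0.95) m or stride swing time
outside (0.23, 0.95) s are masked (bounds inclusive).

## Micro features

Step length uses the inverted-pendulum model
`2·sqrt(2·l·h − h²)` with pendulum length `l = 0.53 × height` and `h`
the peak-to-trough vertical excursion between consecutive ICs, obtained
by double integration of the vertical acceleration with a zero-phase
0.1 Hz highpass after each stage (drift control). `h ≥ l` is flagged
invalid. Step velocity is step length over step time.

Per bout the 16 micro measures are: pace (mean step velocity, mean step
length, SD of swing time), rhythm (mean stance, swing, step, stride
times), variability (SDs of step time, stance, step velocity, step
length, stride time over valid steps; sample SD, needing ≥ 2 steps),
asymmetry (|mean left − mean right| of step, swing and stance time) and
postural control (step-length asymmetry). Asymmetry uses aggregate
left/right means per bout — feet alternate from the first IC of each
bout, labelled right — and is invariant to a global label swap; it is
missing when a foot is absent.

## Macro features

Per two-hour pre-diary window: walking volume (per-bout step counts,
bout lengths, number of bouts, bouts ≥ 10 min), non-walking volume (gap
lengths; gaps ≥ 20/30/50 min), pattern (power-law alpha of walking bout
lengths, mean walking and non-walking times), bout-length variability
(lognormal MLE shape, S2W/S2S) and the per-sample acceleration vector
magnitude.

* Alpha is the continuous power-law MLE
  `1 + n / Σ ln(x_i/x_min)` with `x_min = min(x)`; undefined (missing)
  when all lengths are equal.
* S2 is the population-form lognormal shape MLE
  `sqrt(mean((ln x − mean ln x)²))` — the technique is cited but not
  printed in the source literature; the MLE form is the natural reading
  and is scale-invariant by construction.
* Vector magnitude is computed over **all** samples of the window
  (walking and non-walking) and reported in m/s²; a config switch
  restricts it to walking bouts.
* The bout-length series drop the *mean* statistic when pooled (the
  means already live in the pattern group), avoiding duplicate columns.

## Windowing

Diary entries anchor two-hour windows ending at the completion time;
bouts are selected by their **start** falling inside the window (a bout
running past the entry is included whole). Multi-valued measures are
pooled with nine statistics — mean, SD, variance, sum, min, max, median,
25th/75th percentiles (linear interpolation; SD/variance in sample n−1
form; both conventions configurable) — single-valued measures pass
through tagged `single`. A count-of-values statistic exists behind a
flag and is off by default. A feature row exists only when at least one
walking bout began in the window and at least one label is present;
subjects with no retained rows drop out.

This expansion yields 44 macro columns and, with the 16 per-bout micro
measures × 9 statistics, 144 micro columns. The source feature lists do
not decompose exactly to their printed totals (45 macro, 58 or 57
micro) under any reading we found; the printed lists are implemented
verbatim and the expansion is configurable rather than forced to a
total.

## Mixed-model associations

Each feature is screened with its own binomial random-intercept model:
score = successes out of 6 trials, logit link, fixed intercept and slope
for the standardised feature, Gaussian subject intercept. The marginal
likelihood uses adaptive Gauss–Hermite quadrature (default 10 nodes,
re-centred per subject via a vectorised Newton solve); the unweighted
fit matches lme4's `glmer(..., nAGQ = 10)` to ~5 decimals (tested).

Observations carry inverse score-frequency weights
(`w_i = 1/count(score_i)`, satisfying `Σ w·count = n`). Raw inverse
counts sum to roughly the number of score levels, which would deflate
the likelihood scale and destroy inference, so the weights are rescaled
to mean 1 by default (configurable). The Wald p-value for the slope uses
a subject-clustered sandwich covariance with an m/(m−1) correction —
scale-invariant in the weights and calibrated in the number of
subjects: under a null generator the p < 0.05 rate is 0.045 over 200
fits at 40 subjects.

Two properties of this weighting are worth knowing:

* weighting upweights rare extreme scores, which inflates the fitted
  subject variance even when the generator has none (σ̂ ≈ 0.5 for a true
  σ = 0); the conditional≈marginal R² identity therefore holds for the
  unweighted fit, and the weighted conditional R² should be read as a
  description of the weighted pseudo-population;
* slope estimates under weighting are biased away from the unweighted
  estimand; the sign and ordering of associations are preserved.

R² follows the latent-scale variance decomposition for binomial-logit
models: fixed-effect variance `var(b₁·x)`, subject variance σ̂², residual
π²/3. Marginal R² uses the fixed part alone, conditional adds the
subject variance; the ordering 0 ≤ R²m ≤ R²c ≤ 1 holds on every
converged fit. Feature groups (and, symmetrically, statistics) are
ranked by mean R² with statistically significant entries (p < 0.05,
uncorrected, mirroring the source analysis; Benjamini–Hochberg exists as
an option) counted twice.

## Classification

Two CV designs: five-fold leave-subjects-out (labels binarised at the
fixed threshold: 0–2 low, 3–6 high) and five-fold CV within each subject
(threshold = mean of the training scores, score > mean → high; folds
with a single-class split are skipped and logged). Per fold: training
medians impute missing values, SMOTE oversamples the training minority
class to exact parity (k = min(5, minority−1) neighbours, interpolation
with u ~ U(0,1)), standardisation uses statistics of the resampled
training set (SMOTE before scaling, following the stated processing
order), rows are shuffled. The test split receives only
training-derived imputation and scaling. SMOTE is implemented
in-package (k-NN interpolation); no resampling library is a dependency.

Grid search is exhaustive over the printed grids — SVM-RBF C, γ ∈
{0.001…1000} (49 combinations), kNN k ∈ {1…15} (9), random forest
trees ∈ {5…500} × max-features ∈ {√N, log₂N, N} (18), Gaussian NB (1) —
with inner 10-fold stratified CV scored by balanced accuracy (the inner
fold count shrinks to the minority class size when needed). The random
forest predicts from the average of the trees' probabilistic
predictions. High fatigue is the positive class; precision, recall and
balanced accuracy come from explicit confusion counts (cross-checked
against scikit-learn).

A single run-level seed drives subject shuffling, fold splits, SMOTE,
grid-search CV and the estimators.

## Feature importance

The LightGBM ranker trains a boosted-tree classifier per stratified fold
and normalises each feature's summed split gain by the total gain
(importances sum to 1 per fold; a never-used feature scores exactly 0);
fold values are averaged. Permutation importance is the drop in balanced
accuracy under K = 5 seeded permutations of one column, measured on a
held-out split and averaged over the four classifier families; permuting
a constant column leaves the matrix unchanged, so its importance is
exactly 0.

## Synthetic cohorts

The study data are not deposited, so every stage is validated against a
generator with recorded ground truth. The signal model is deliberately
minimal — it exercises the published thresholds and makes parameters
recoverable; it is not a biomechanical simulation:

* Rest is −1 g on VV plus white noise (default SD 0.01 g, giving rest
  windows a summed-SD around 0.03 g, safely under the 0.05 g movement
  threshold).
* Walking bouts draw lengths from a continuous Pareto law (default
  α = 1.8 above 5 s, capped at 600 s for realism — free-living walking
  is dominated by short bouts); rest gaps are lognormal (μ = 4.0 log-s,
  σ = 0.9) floored at 6 s so distinct bouts stay separable by the 2-s
  merge rule. Estimator-consistency checks use the uncapped sampler.
* Each step k of duration T_k carries
  `acc_VV = (h_k/2)·ω_k²·(cos θ − 0.2·cos 2θ)/9.81` (θ the step phase,
  ω_k = 2π/T_k). Two properties motivated this template: the harmonics
  are symmetric in θ, so the zero-phase detection chain places the IC
  exactly at θ = 0 (the vertical-displacement minimum, where true ICs
  are recorded); and cos 2θ takes equal values at θ ∈ {0, π}, so the
  peak-to-trough excursion of the doubly integrated signal equals h_k
  exactly. h_k is the pendulum relation inverted at the injected step
  length, so step length is recoverable end-to-end. AP carries a
  quarter-phase copy at 0.4 amplitude, ML a stride-frequency copy at
  0.25.
* Alternating steps differ in length by `asymmetry_frac`; step
  durations jitter with a configurable CV (default 2%); subjects draw
  cadence, step length, height and a diary intercept from Gaussians.
* Whole days flip sign with `flip_probability`; `missing_frac` of
  samples are blanked in contiguous blocks placed inside rest gaps
  (device-off at rest), keeping bout ground truth valid and the
  walking + non-walking + missing = total identity intact.
* Diary scores are Binomial(6, p) with
  logit p = intercept + subject effect + β·z(feature), where the feature
  is the windowed true gait measure (mean step velocity by default)
  standardised over the cohort — exactly the family the association
  stage fits, so calibration studies have a matched generative model.
  Non-response is simulated (default response probability 0.9).
  `simulate_association_table` exposes the score model directly for
  calibration studies that do not need raw signals.

A "day" spans a configurable wear window (default 09:00–22:00) rather
than 24 h, keeping cohort simulations tractable at 100 Hz.

What the generator does **not** emulate: disease-specific gait
signatures, turning, posture transitions, realistic double-support
timing (the detected stance fraction is a property of the template, not
physiology), sensor drift or non-Gaussian noise. Passing recovery tests
therefore demonstrates correctness of the published computations, not
clinical validity on real recordings.

## Problem sizes and tolerances

Tests and the acceptance script use desk-scale problems chosen as
sensible defaults: detector recovery on 5 subjects × 1 day (09:00–13:00
wear, noise 0.005 g) — bout counts match exactly, median IC error ≈5 ms,
step time within 0.1%, step length within ~4%; estimator consistency on
10⁴ draws (α within ±0.02, S2 within ±0.01); mixed-model calibration
with 200 null fits at 40 subjects and sign recovery at 60 subjects with
a slope sized for ~80% power; classification on direct feature tables
(20 subjects × 24 windows for permutation nulls, 14 × 30 for the
strongly coupled condition, reduced hyperparameter grids for the null
checks where grid content is irrelevant). Equation-level oracles are
asserted to 1e−9; stochastic checks use fixed seeds and tolerances
stated with each test.

## Known limitations

* The binomial-trials encoding of the 0–6 Likert score is an
  interpretation (ordinal mixed models are out of scope by design).
* Weighted mixed-model R² and slopes describe the weighted
  pseudo-population (see above).
* The CWT scale and the stance fraction of the synthetic template are
  conventions; detected stance/swing on real data will differ.
* The intrasubject binarisation classifies scores equal to the training
  mean as low (`> threshold → high`); ties at the threshold are
  otherwise arbitrary.
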