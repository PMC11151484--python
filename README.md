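# gaitfatigue

Free-living gait analysis for momentary fatigue research: a tested
pipeline from raw lower-back triaxial accelerometry (100 Hz, ±8 g) and
patient-reported fatigue diaries (physical and mental fatigue, Likert
0–6, up to four entries a day) to walking bouts, gait events, pooled
gait features and two complementary analyses of the gait–fatigue
relationship. It is aimed at digital-health researchers working with
wearable sensors in neurodegenerative and immune-mediated disease
cohorts, where self-reported fatigue is the clinical anchor and gait is
the candidate objective correlate.

## What it computes

**Walking bouts.** The signal is lowpass filtered (Butterworth, 17 Hz)
and cut into 0.1-s windows; a window is *upright and moving* iff
σ_VV + σ_ML + σ_AP ≥ 0.05 g and mean(Acc_VV) ≤ −0.77 g. Active runs
separated by < 2 s merge; runs < 2 s are dropped.

**Gait events.** Within each bout, the vertical axis is detrended,
filtered (20 Hz), integrated and differentiated with a Gaussian CWT:
initial contacts are the retained minima, final contacts the retained
maxima of a further differentiation. Steps are delimited by consecutive
ICs; feet alternate from the first IC (right). Per step,

    stance_i = FC_{i+1} − IC_i,  stride_i = IC_{i+2} − IC_i,
    swing_i = stride_i − stance_i,
    step length = 2·sqrt(2·l·h − h²),  l = 0.53 × height,

with h the vertical excursion of the doubly integrated acceleration
(inverted-pendulum model).

**Features.** Per two-hour pre-diary window: *macro* measures of
activity (bout counts and lengths, power-law alpha
`α = 1 + n/Σ ln(x_i/x_min)` of bout lengths, lognormal bout-length
variability S2, acceleration vector magnitude) and *micro*
spatiotemporal measures (pace, rhythm, variability, asymmetry, postural
control), pooled with nine statistics.

**Associations.** One binomial random-intercept GLMM per feature
(score = successes out of 6 trials, logit link, subject random
intercept, adaptive Gauss–Hermite quadrature, inverse score-frequency
weights), summarised by marginal and conditional R² (latent-scale
variance decomposition with π²/3 residual variance) and double-weighted
group rankings.

**Classification.** Low vs high fatigue under intersubject
(leave-subjects-out, fixed threshold 0–2 vs 3–6) and intrasubject
(within-subject folds, training-mean threshold) cross-validation, with
training-median imputation, SMOTE to class parity, standardisation and
exhaustive grid search over SVM-RBF, kNN, random forest and Gaussian
naive Bayes, scored by balanced accuracy; plus LightGBM split-gain and
permutation feature importance.

Because the motivating study's recordings are not publicly deposited,
the package ships a synthetic-data generator
(`gaitfatigue.synthetic_data`) that emulates the protocol with known
ground truth — bout boundaries, IC times, step lengths and a
configurable latent gait–fatigue coupling — so every stage is validated
by parameter recovery. See `docs/methods.md` for the signal model and
its limits.

## Worked example

```python
import numpy as np
from gaitfatigue import SimConfig, simulate_cohort, build_dataset, fit_glmm
from gaitfatigue.bout_detection import detect_bouts
from gaitfatigue.windowing import feature_columns

cfg = SimConfig(n_subjects=4, days=1, day_start_h=9, day_end_h=14,
                coupling_beta=0.8, seed=7)
recordings, diary, truth = simulate_cohort(cfg)

bouts = detect_bouts(recordings[0])
walking = [b for b in bouts if b.kind == "walking"]
print(f"subject {recordings[0].subject_id}: {len(walking)} walking bouts, "
      f"median length {np.median([b.length_s for b in walking]):.1f} s")

dataset = build_dataset(recordings, diary)
print(f"modelling table: {len(dataset)} diary windows x "
      f"{len(feature_columns(dataset))} features")

res = fit_glmm(dataset["micro__pace__step_velocity_mps__mean"],
               dataset["pf_score"], dataset["subject_id"])
print(f"step velocity vs physical fatigue: beta={res.beta:.3f} "
      f"p={res.p_value:.3g} R2m={res.r2_marginal:.4f} R2c={res.r2_conditional:.4f}")
```

prints

```
subject S000: 162 walking bouts, median length 10.8 s
modelling table: 8 diary windows x 188 features
step velocity vs physical fatigue: beta=1.362 p=0.0846 R2m=0.3509 R2c=0.3776
```

The first line is the detector's view of one simulated day (many short
bouts, as in free living). The table has one row per diary entry that
had at least one walking bout start in its preceding two hours, with 44
macro and 144 micro feature columns. The GLMM line reads: one SD of mean
step velocity shifts the physical-fatigue logit by 1.36 (the generator
coupled this feature positively); fixed effects alone explain ~35% of
latent-scale variance here, subjects add ~3% — at this toy size the
p-value is not yet significant.

A `gaitfatigue` CLI wraps the same stages (`simulate`, `ingest`,
`detect-bouts`, `detect-steps`, `build-dataset`, `associate`,
`classify`, `importance`); run `gaitfatigue --help`.

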