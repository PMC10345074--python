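# Methods

This note records the models, conventions and numerical choices behind
`noctidip`, in the order data flows through the pipeline, together with
what the synthetic generator does and does not emulate.

## Data model

The raw unit is a beat-annotation series: absolute beat times, the RR
interval (ms) ending at each beat, and a per-beat label (`N` normal/sinus,
`P` paced, `E` ectopic, `O` other). Timestamps are time-zone-naive local
clock times throughout — the analysis is circadian, so everything is
clock-relative. Clinical covariates (age, sex, NIHSS, comorbidity flags,
serial troponin in ng/l, GFR, discharge mRS, admission time) ride in a
one-row-per-patient table; any field may be missing and is marked so
explicitly (NaN / empty cell).

## Cohort selection

Records are first trimmed to `[admission, admission + 48 h)` (half-open).
The exclusion cascade then runs in a fixed order with first-failure
accounting, so flow-chart counts are well defined and always conserve the
initial cohort:

1. **Insufficient normal beats** — fewer than `min_normal_beats` (default
   5,000 over 48 h, ≈10% duty cycle at 60 bpm). The insufficiency threshold
   is site-dependent in practice, so it is configuration, not a constant.
2. **Missing required covariates** — default set: age, sex, NIHSS, GFR,
   discharge mRS, troponin.
3. **Atrial fibrillation diagnosis** — AF makes RR statistics incomparable;
   the criterion can be disabled for robustness analyses that re-admit AF
   patients.
4. **Majority-paced rhythm** — > 50% paced beats. Most paced patients
   already fail criterion 1 after paced-beat removal; this step catches the
   remainder.

Only `N`-labeled beats enter the metrics. Stored RR values are used as
annotated; intervals are never re-derived across the holes left by removed
beats. Instead, successive-difference statistics skip any pair whose
inter-beat time jump exceeds twice the segment's median RR, which covers
both removed beats and recording gaps and prevents artifactual RMSSD
spikes.

Troponin coding: 0 — all samples below the 14 ng/l upper reference limit;
1 — at least one sample above it; 2 — an elevated sample plus a second
sample differing from it by ≥ 20% of the elevated value (acute rise or
fall; requires ≥ 2 samples). Outcome dichotomy: mRS 0–2 = good
(independent living), 3–6 = unfavorable (dependency, including death).

## Segment metrics and circadian profiles

Beats are binned on the wall-clock 5-min grid ([hh:00, hh:05), …); the
grid is clock-aligned, not admission-aligned, because hour-of-day profiling
requires clock alignment. Per segment with ≥ 30 beats (again ~10% duty at
60 bpm; segments below the quorum yield missing metrics):

* HR = median over beats of 60000/RR (midpoint convention for even
  counts);
* SDNN = population standard deviation of RR;
* RMSSD = root mean square of successive RR differences over valid pairs
  (gap rule above), requiring ≥ 2 valid pairs;
* LF/HF: the tachogram (beat time → RR) is interpolated with a cubic
  smoothing spline (smoothing 0 = interpolating, configurable), sampled on
  a uniform 4 Hz grid, mean-removed, and passed to a periodogram; band
  power integrates the PSD with the rectangle rule over [0.04, 0.15) Hz
  (LF) and [0.15, 0.4) Hz (HF), in ms². Preconditions: segment span
  ≥ 150 s (to resolve 0.04 Hz) and ≥ 16 beats. The 4 Hz rate is the
  standard HRV resampling choice (Nyquist 2 Hz ≫ 0.4 Hz); "resampling by a
  factor of 4" conventions differ between implementations, so the rate is
  configurable.

Hourly profile values are medians across the segments of each clock hour,
pooled over both recording days (up to 24 segments/hour); an hour is
reported only when ≥ 3 segments contribute. The median aggregator matches
the robust 5-min median convention; LF/HF is reported as the ratio of the
band powers where HF > 0.

## Nocturnal dip and hourly tests

Per patient, with day = clock hours {10…16} (10:00–17:00) and night =
{22, 23, 0…4} (22:00–05:00), both 7-hour half-open windows:

    percent_decline = 100 · (mean_day − mean_night) / mean_day

Window means weight available hourly values equally (hourly values are the
unit of analysis); negative values indicate reverse dipping. Window means
are computed per patient and then averaged, which is what makes a group
SEM well defined. Group contrasts per clock hour use two-sided
Mann–Whitney U tests on patient-level hourly values with a fixed Bonferroni
factor of 24 regardless of how many hours were testable (conservative);
hours where a group contributes < 2 values are reported untested.

## Propensity matching

Group membership (unfavorable = 1) is modeled by unpenalized logistic
regression on the matching covariates (default age + NIHSS; an age-only
preset supports robustness analyses). Perfect separation is detected when
the fitted scores split the classes exactly; the model then falls back to a
ridge penalty of 1e-4 with a warning, keeping small simulated cohorts
runnable. Matching is greedy 1:1 nearest-neighbor on the logit propensity,
minority group processed in seeded random order, without replacement; a
pair is kept only if its |logit difference| is within caliper × SD(logit
propensity) (default caliper 0.2, the conventional rule; a raw-probability
caliper scale is available). Balance is reported as standardized mean
differences, SMD = Δmean / √((s₁² + s₂²)/2), before and after matching;
zero pooled SD yields SMD 0 with a degenerate-covariate flag.

## Outcome models

Features: age, sex (0/1), NIHSS, hypertension, diabetes, prior MI, CAD,
pneumonia, ordinal troponin category (0/1/2), GFR, optionally nocturnal HR
(mean hourly HR over the night window). Patients with any missing cell are
dropped with logged counts.

Evaluation is nested stratified cross-validation: per shuffle, a stratified
outer 5-fold split; per outer fold, features are standardized to zero
mean/unit variance with training-fold statistics only (fitting the scaler
globally would leak test information — negligible at n ≈ 300 but
correctness matters), an exhaustive inner stratified 5-fold grid search
maximizes AUC, the winner is refit on the outer-training fold, and AUC is
measured on the held-out fold. Shuffles re-seed both levels. Inner AUC is
the tuning metric, matching the reported performance metric. Candidates
are visited simplest-first (larger regularization / smaller depth) and ties
keep the earlier candidate, making the search deterministic; a shuffle
whose split drops a class is retried with an offset seed.

Hyperparameter grids: logistic regression tunes the inverse regularization
strength over a fixed 50-point log-spaced grid (0.1 … 1000). Gradient
boosting uses LightGBM with tree depth {2, 4, 6}, learning rate 20 points
in [0.03, 0.3], bagging fraction 3 points in [0.6, 1], and L2 leaf
regularization {3, 10, 100, 500}; 100 trees, `deterministic=True`,
single-threaded. A reduced same-axes grid (`ModelSpec.small_boosting`) is
provided for quick runs.

Feature importance: logistic — absolute standardized coefficients;
boosting — mean absolute per-sample Shapley attribution from LightGBM's
exact tree-path contributions. Both are scaled to unit Euclidean norm; an
all-zero vector is returned unnormalized and flagged by its zero norm.
Configurations (with vs without nocturnal HR) are compared by a two-sample
t test on the per-shuffle mean AUCs.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* **Circadian HR.** Instantaneous target
  `h(t) = baseline_day_hr · (1 − dip_fraction · w(t))`, where w ramps
  0→1 / 1→0 with a piecewise-cosine of `transition_minutes` (default 60)
  centred on the night-window boundaries (22:00 and 05:00). The cosine
  ramp avoids discontinuities that would leak broadband power into the
  LF/HF bands; centring it on the boundary makes the hourly-median dip
  estimate track the nominal dip fraction closely. Each RR interval is
  `60000/h(t)` plus LF and HF sinusoids and Gaussian noise, floored at
  300 ms and capped at 2000 ms (physiological plausibility; guarantees
  positive intervals). Beat times are the cumulative sum of intervals —
  the recurrence is sequential, so the kernel is numba-compiled.
* **Artifacts.** Ectopic beats (independent Bernoulli per beat) take the
  classic premature + compensatory shape (0.6× RR, following beat 1.4×);
  recording gaps remove beats without shifting times; paced patients carry
  ~90% `P` labels; AF-like patients get `RR = exp(AR(1))` rescaled to mean
  800 ms — irregularly irregular, serially correlated, no circadian
  structure — plus the AF diagnosis flag.
* **Covariates and outcome.** Age, NIHSS (negative binomial,
  overdispersed), sex, comorbidity prevalences, GFR and serial troponin are
  drawn per configurable distribution parameters, loosely calibrated to a
  typical elderly stroke-unit population (mean age ~74.5, median NIHSS ~5,
  hypertension ~84%) with additive shifts creating the age/NIHSS imbalance
  that motivates matching. Discharge mRS is drawn through a logistic link
  on standardized age, NIHSS, the patient's realized dip fraction,
  nocturnal HR, and comorbidity count; the two generator groups fix
  physiology (default dip fractions 0.105 vs 0.063, day baselines 76.3 vs
  78.4 bpm, per-patient jitter SD 0.02 / 3 bpm), while downstream outcome
  labels always come from the mRS dichotomy. All-zero coefficients give
  P(unfavorable) = 0.5 exactly.

Identical specs (including seed) produce bit-identical cohorts; all
randomness flows from explicit seeds through `numpy` SeedSequences.

What the generator does **not** emulate: real RR noise is neither additive
Gaussian nor a pair of pure sinusoids (the sinusoid-plus-noise model is a
stated convention); no ECG waveforms, no drug effects, no activity- or
sleep-driven nonstationarity beyond the single circadian dip, no
correlation between artifact burden and outcome. Passing tests therefore
demonstrate the pipeline's correctness and statistical calibration under
the assumed structure, not clinical performance on real monitor data.

## Problem sizes in the test and acceptance suites

Simulation-based checks choose sizes that make the statistical criterion
meaningful: dip-fraction recovery uses 10 cohorts of 100 + 100 patients
with 24 h recordings and HR-only metrics (the dip statistic needs no
spectral step); the family-wise-error calibration uses 200 directly
synthesized null cohorts of 30 + 30 hourly profiles; matching balance uses
100 covariate-only cohorts of 300 + 300 — at materially smaller cohorts
the sampling noise of an SMD estimate (≈ √(2/n)) exceeds the 0.1 balance
bar regardless of matching quality; ML calibration averages five
independent label permutations because shuffle means within one
permutation are correlated. The acceptance script simulates 225 + 225
patients (48 h each) and evaluates 15 shuffles per configuration with the
full logistic grid and the reduced boosting grid.

## Known limitations

* The spectral estimator is a plain periodogram on a spline-resampled
  tachogram; Welch or Lomb–Scargle alternatives would trade variance for
  bias differently and are not implemented.
* Greedy nearest-neighbor matching is order-dependent (hence the seeded
  order); optimal matching is out of scope.
* The nested CV retry rule handles degenerate splits only by re-seeding;
  cohorts below 10 patients per class are rejected outright.
* Hourly values assume the 5-min grid and the 3-of-24 quorum; other
  segmentations require re-deriving the quorum.
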