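# noctidip

Circadian heart-rate profiling and nocturnal-dipping analysis for
continuously monitored stroke-unit patients — from beat-to-beat ECG
annotations to outcome prediction.

## The problem

Stroke disturbs autonomic regulation of the heart. One visible signature is
a blunted *nocturnal dip*: in healthy circadian physiology, heart rate (HR)
falls at night, and patients who lose that fall ("non-dippers") tend to do
worse. Stroke units record continuous monitor data, so the full circadian
HR/HRV pattern is available — but turning raw beat annotations into a
defensible group comparison requires careful filtering (normal beats only,
no atrial fibrillation, no paced rhythms), robust segment statistics,
confounder matching, and leak-free model evaluation.

`noctidip` implements that whole chain for beat-annotation data
(timestamp, RR interval in ms, beat label), plus a synthetic-cohort
generator with the same statistical structure so every stage is testable
without patient data.

## What it computes

* **Segment metrics.** The normal-beat series of the first 48 h after
  admission is cut into wall-clock 5-min segments. Per segment: median HR
  (bpm), SDNN (population SD of RR, ms), RMSSD (root-mean-square of
  successive RR differences, ms, skipping pairs that straddle removed beats
  or gaps), and LF/HF band power (spline-interpolated RR tachogram,
  resampled at 4 Hz, periodogram PSD integrated over 0.04–0.15 Hz and
  0.15–0.4 Hz, ms²).
* **Circadian profiles.** Hour-of-day medians across segments; an hour
  counts only if ≥ 3 of its possible 24 segments are available.
* **Nocturnal dip.** Per patient,
  `percent_decline = 100 · (HR_day − HR_night)/HR_day` with day =
  10:00–17:00 and night = 22:00–05:00; groups summarized as mean ± SEM and
  compared per clock hour by Mann–Whitney U with Bonferroni ×24.
* **Matching.** Propensity scores (logistic model of outcome group on age
  and NIHSS), greedy 1:1 nearest-neighbor matching on the logit scale
  without replacement, caliper 0.2 SD, with standardized-mean-difference
  balance reporting.
* **Outcome prediction.** Dichotomized discharge outcome (mRS 0–2 good vs
  3–6 unfavorable) predicted from clinical features ± the nocturnal HR
  feature, by nested stratified 5-fold cross-validation (inner grid search,
  repeated shuffles) for logistic regression and gradient-boosted trees;
  unit-norm feature importances (standardized coefficients / Shapley
  tree-path attributions) and a two-sample t test comparing the with-HR and
  without-HR configurations.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/03_nocturnal_dipping.py` (50 + 50 simulated patients,
24 h of monitoring each) prints:

```
      group  mean_percent_decline      sem  n
       good             10.247853 0.355248 54
unfavorable              6.554038 0.395664 46

hours with Bonferroni-significant HR group difference: [0, 1, ..., 23]
```

Patients with good outcome dip ~10% at night, the unfavorable group only
~6.6% — the pipeline recovers the generator's dip fractions (0.105 / 0.063)
from raw beat series. `python examples/05_outcome_prediction.py` then shows
the prediction gain from the nocturnal HR feature:

```
AUC without nocturnal HR: 0.674 +/- 0.009
AUC with nocturnal HR   : 0.766 +/- 0.013
two-sample t over shuffles: t=-12.86, p=1.3e-06
```

with `nocturnal_hr` ranked first in the unit-norm importance vector.

A thin CLI wraps the pipeline for shell use:

```bash
noctidip simulate --config cohort.yaml --out sim/
noctidip run-all  --config run.yaml   --out runs/demo
noctidip report   --run-dir runs/demo
```

## Layout

```
src/noctidip/
  synthetic.py   # synthetic cohorts: circadian RR generator, artifacts, outcomes
  ingest.py      # beat/covariate I/O, validation, exclusion cascade
  hrv.py         # 5-min segment metrics and circadian profiles
  dipping.py     # nocturnal dip statistic and hourly group tests
  matching.py    # propensity-score matching and balance reporting
  model.py       # nested-CV prediction, importances, model comparison
  pipeline.py    # end-to-end orchestration with reproducible run directories
  plots.py, cli.py
docs/methods.md  # modeling assumptions, parameter choices, limitations
```
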