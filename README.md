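# nocisense

Ultra-short-window (≤10 s) processing of wearable electrodermal activity
(EDA) and photoplethysmography (PPG) for classifying pain and
pain-anticipation anxiety state.

## The problem

Clinical pain and anxiety monitoring leans on visual-analog-scale (VAS)
self-report, which fails when a patient cannot respond and is shaped by
context and expectation. Both pain and the anxiety of anticipating pain
raise sympathetic nervous system activity, which two wearable signals read
out non-invasively: skin conductance (EDA, from eccrine sweat-gland
activity) and pulse rate variability (PRV, from PPG pulse timing). Most
established EDA/PRV methods need minutes of signal; a bedside monitor needs
an answer from seconds. This package implements a complete
ultra-short-window pipeline — decomposition, time-frequency sympathetic
indices, pulse-chain processing, windowed feature extraction, and
subject-held-out classification — together with a synthetic cohort
generator that emulates a two-modality pain protocol (thermal grill
illusion and transcutaneous electrical stimulation) so every stage is
testable end to end.

## The model in brief

**EDA (4 Hz, µS).** After zero-phase low-pass filtering, the signal is
split as

    y(t) = SCL(t) + SCR(t) + r(t),      SCR = (q * h)(t),   q ≥ 0

where the phasic component SCR is a sparse non-negative sudomotor driver
`q` convolved with a biexponential (Bateman) kernel
`h(t) = e^(−t/τ_slow) − e^(−t/τ_fast)` (τ_fast = 0.7 s, τ_slow = 2.0 s)
and the tonic level SCL is a smooth cubic-spline baseline; both are
recovered jointly from a ridge-regularized non-negative deconvolution. A
uniform complex-demodulation filter bank (bandwidth 0.04 Hz, centers
(2k−1)·0.04 Hz) yields per-band instantaneous amplitudes; the amplitudes
of the bands covering 0.08–0.24 Hz — where sympathetic arousal
concentrates — sum to **TVSymp** (normalized to unit variance over the
recording), and **MTVSymp(t) = max(0, TVSymp(t) − mean of the trailing
5 s)** isolates short-lived surges.

**PPG (50 Hz).** Band-pass 0.5–8 Hz, envelope-gated systolic peak
detection (squared-signal envelopes at pulse and beat scale), deterministic
false-peak correction, then beatwise HR = 60000/PPI interpolated to 4 Hz by
monotone PCHIP (no overshoot).

**Features per 10 s window** (anticipation = countdown before the
stimulus; stimulation = the stimulus itself): NSSCR (0.05 µS threshold
crossings), SCL mean/variance/max/slope, Hjorth Activity/Mobility/
Complexity, Welch total power and sympathetic-band power (EDASymp),
TVSymp/MTVSymp means and maxima (plus power-normalized variants),
slope-to-peak trends, mean HR, HR range, PPI s.d. and RMSSD — each raw and
baseline-subtracted against a pre-test rest window.

**Classification.** Binary targets: pain (own-trial pain VAS ≥ 5 vs 0, or
stimulation level ≥ 2 vs sham) on stimulation windows, anxiety
(previous-trial pain VAS or level, a proxy motivated by the strong
anxiety/previous-pain association) on anticipation windows. Subject-wise
standard scaling, median imputation, greedy backward feature elimination,
and a successive-halving randomized hyperparameter search are fit inside
each leave-one-subject-out (LOSO) fold; performance is pooled balanced
accuracy BAC = (sensitivity + specificity)/2 and ROC AUC. Model families:
logistic regression, linear SVM, random forest, k-NN, gradient-boosted
trees. A final model aggregates fold-level selections and is explained by
additive per-feature attributions (exact for linear models, permutation-
sampling Shapley otherwise).

## Worked example

```bash
nocisense simulate -o cohort/ --subjects 3 --seed 2
nocisense extract cohort/S000 cohort/S001 cohort/S002 -o feats.csv
nocisense train feats.csv --target stim_level --model lr --seed 3 -o result.json
nocisense report result.json
```

prints

```
target: stim_level   model: lr
metric           value
sensitivity      1.000
specificity      1.000
bac              1.000
auc              1.000
folds: 3 (0 skipped)
```

Each of the 3 simulated subjects completes 3 thermal-grill and 5
electrical-stimulation trials; `extract` writes one row per (subject,
trial, phase) — 48 rows — and `train` runs the full LOSO pipeline on the
sham-vs-level≥2 target. At the generator's default (strong) effect sizes
the three-subject toy problem is perfectly separable, hence the 1.000s; on
larger cohorts with default noise the pooled LOSO AUC is typically in the
0.9–1.0 range for linear models.

The same pipeline is available as a library:

```python
from nocisense import (CohortConfig, generate_cohort, build_feature_table,
                       LabelSpec, loso_cv)
sessions, truth = generate_cohort(CohortConfig(n_subjects=20, seed=7))
table = build_feature_table(sessions)
cv = loso_cv(table, LabelSpec.for_target("stim_level"), "lr", seed=7)
print(f"BAC {cv.bac:.3f}  AUC {cv.auc:.3f}")
```

## Layout

- `src/nocisense/signal_io.py` — session data model, CSV+JSON layout, validation
- `src/nocisense/eda.py` — filtering, tonic/phasic decomposition, VFCDM, TVSymp/MTVSymp, Welch summaries
- `src/nocisense/ppg.py` — filtering, envelope peak detection, false-peak correction, 4 Hz HR
- `src/nocisense/features.py` — windowing and the feature registry
- `src/nocisense/ml.py` — labeling, scaling, selection, search, LOSO, attribution
- `src/nocisense/synth.py` — the synthetic cohort generator
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
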