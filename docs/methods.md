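# Methods

This note records the modeling and numerical choices behind the package,
what the synthetic cohort does and does not emulate, and the known
limitations. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` compute.

## Signal model and decomposition

Skin conductance is modeled as tonic level + phasic responses + residual,
`y = SCL + SCR + r`, with `SCR = q * h` for a non-negative sudomotor
driver `q` and a Bateman kernel `h(t) = e^(−t/τ_slow) − e^(−t/τ_fast)`.
Defaults τ_fast = 0.7 s, τ_slow = 2.0 s are standard sudomotor time
constants; the kernel is truncated at 20 s (≥ 10 τ_slow, relative
truncation error < 5·10⁻⁵) and peak-normalized so driver amplitudes carry
µS units. The tonic basis is a cubic B-spline with knots every 10 s, which
spans constants and linear drift; 10 s is slow enough that single SCRs
(1–3 s rise) cannot be absorbed by the baseline yet fast enough to track
thermoregulatory drift.

The joint estimate solves

    min_{q ≥ 0, c}  ‖(q * h) + B c − y‖² + λ‖q‖² ,   λ = 0.05.

The spline coefficients are eliminated through the orthogonal projector
onto span(B)⊥ and the driver is found by FISTA projected gradient descent
with FFT convolutions; the Lipschitz step uses the bound
‖A‖₂ ≤ Σₖ h[k] for the causal Toeplitz convolution operator. Convergence
is declared when the projected-gradient norm falls below a scale-relative
threshold; non-convergence raises an error carrying the iteration count
and final optimality. The ridge λ trades driver sparsity against
amplitude bias; 0.05 recovers 100% of injected pulses ≥ 0.1 µS within 1 s
on the synthetic benchmark while keeping phasic energy on pulse-free tonic
ramps below 10⁻⁶ of signal energy. The `sparse` method variant prunes
driver samples below 2% of the maximum and refits the surviving support by
non-negative least squares, giving an impulse-like driver; both variants
define the residual as the exact closure `r = y − SCL − SCR`, so
reconstruction is exact by construction and tests assert it at 1e-9.

## Time-frequency sympathetic indices

The filter bank uses fixed-frequency complex demodulation: centers
(2k−1)·0.04 Hz for k = 1..25 (0.04–1.96 Hz), zero-phase 4th-order
Butterworth low-pass at the 0.04 Hz bandwidth, amplitude 2|z_k|. With this
geometry the second and third components (0.12, 0.20 Hz) exactly tile the
0.08–0.24 Hz band used for TVSymp. An instantaneous-frequency refinement
stage is deliberately not the tested default: for amplitude-sum indices
over a fixed band, fixed demodulation is equivalent in the mean and much
easier to verify. Two numerical facts matter for users:

- At band crossovers each neighbor passes the content with quadratic gain
  1/2 (zero-phase doubling of the −3 dB point), so summed reconstructions
  are near-complete: measured interior reconstruction error ≈ 3% RMS on
  band-limited noise. Within ~25 s of the recording edges the 0.04 Hz
  low-pass transient dominates; completeness and envelope properties are
  therefore asserted on the interior.
- TVSymp is normalized to unit standard deviation over the **entire
  recording**, not per segment; per-segment normalization would erase the
  between-window amplitude differences the features rely on. A constant
  amplitude sum yields all-zero TVSymp.

MTVSymp subtracts the trailing 5 s mean (window includes the current
sample; expanding at the start so the series is defined from sample 0) and
floors at zero. The implementation is a cumulative-sum identity checked
against a literal loop at 1e-9.

EDASymp integrates the Welch PSD over 0.045–0.25 Hz by default. The
narrower 0.08–0.24 Hz quote applies to TVSymp's band selection; both bands
are configurable, and for ≤10 s windows the Welch estimate degenerates to
a single-segment periodogram (the contract demands an explicit error,
rather than silent zero-padding, when a caller requests a segment longer
than the data).

## Pulse chain

PPG is band-passed 0.5–8 Hz (zero-phase, 4th order): the high-pass removes
baseline wander and the low-pass keeps systolic upstroke and dicrotic
notch. Peak detection gates candidate blocks where a pulse-scale (0.125 s)
moving average of the squared signal exceeds a beat-scale moving average
plus a small amplitude-scaled offset (which rejects flat records); each
block ≥ 0.1 s wide contributes its filtered-signal maximum as one systolic
peak. The beat-scale window is 1.3 s: a shorter (~0.67 s) window lets the
envelope dip between systole and dicrotic notch at 45–60 bpm and
double-counts the notch, which the 1.3 s window eliminates across
45–120 bpm without merging beats at 120 bpm.

False-peak correction replaces manual editing with two deterministic
rules: merge a spuriously split beat when removing the extra peak restores
an interval near the running median (ratio 0.4 over the median of the 5
previous valid intervals), then flag — never fabricate — intervals outside
300–2000 ms or jumping beyond the ratio. Invalid intervals are excluded
from PRV features; with fewer than two usable intervals in a window the
PPI features are missing, not zero, and are median-imputed inside training
folds only.

Beatwise HR is placed at interval midpoints (symmetric assignment
minimizes phase bias) and interpolated to the common 4 Hz grid with PCHIP,
whose monotone construction cannot overshoot the beatwise HR range — the
property tests exercise 1000 random interval sequences.

## Features

All windowed features live in a closed registry (26 raw features, each
with a baseline-subtracted `_bn` variant); extraction refuses to emit
anything outside it. Conventions: population variance (divide by N) for
Activity and PPI s.d.; Hjorth derivatives are first differences scaled by
the sampling rate; NSSCR counts upward threshold crossings of the phasic
component at 0.05 µS and requires a prior sub-threshold sample; the
slope-to-peak anchor is the last local minimum before the global maximum,
falling back on a monotone rise to the maximum-curvature point (largest
second difference) and finally to the window start. Windows shorter than
5 s (early withdrawals) are dropped with a warning; anticipation and
stimulation windows are at most 10 s by protocol. Ramp-down intervals are
segmented but not featurized by default.

## Labeling and evaluation

"Medium or higher" is operationalized as VAS ≥ 5 and "none" as VAS = 0,
with scores 1–4 excluded by default (configurable); the level analog is
sham (0) negative, level ≥ 2 positive, level 1 excluded. Anxiety targets
label anticipation windows by the previous trial within the same modality
block; the first trial of each block has no predecessor and is dropped.

Subject-wise standard scaling follows the within-subject definition: each
row is scaled by its own subject's mean and s.d. across that subject's
windows. This imports information from a test subject's other windows into
LOSO evaluation; it is retained as the default because it is the
definition the pipeline is built around, and because the alternative
(train-statistics scaling) changes the meaning of the features rather than
merely the protocol. The backward feature elimination drops the
lowest-importance feature while inner grouped-CV balanced accuracy does
not decrease (ties prefer fewer features); the hyperparameter search
samples up to 8 grid candidates and halves them by factor 3 over
increasing subject budgets, ending on the full training set. All inner
evaluation is grouped by subject and scored by balanced accuracy, the
class-imbalance-tolerant metric used throughout. Decision scores are
Platt-calibrated per fold so the 0.5 threshold is meaningful across model
families; pooled predictions give a single ROC, and per-fold results are
retained in the `CVResult`.

Feature attribution is additive: for linear models exactly
`w_j (x_j − mean(x_j))` on the decision scale; otherwise a
permutation-sampling Shapley approximation against the feature-mean
reference, whose per-permutation telescoping guarantees the efficiency
property exactly and whose per-feature values converge as the number of
sampled permutations grows (default 30).

## The synthetic cohort

The generator emulates the study protocol exactly in structure: per
subject, a 30 s rest (baseline window inside it), three thermal-grill
trials at levels 0, 2, 1, then five electrical-stimulation trials at
levels 2, 0, 1, 3, 4; each trial is 10 s anticipation, 10 s stimulation,
10 s ramp-down, 30 s recovery, recorded continuously at 4 Hz (EDA) and
50 Hz (PPG).

Physiology is reduced to a single latent arousal per trial, monotone in
level (defaults: thermal 0/1.0/1.6, electrical 0/0.8/1.6/2.4/3.2 before
log-normal subject gain, σ = 0.15). Arousal drives: Poisson sweat-burst
rate (0.05 + 0.25·arousal events/s, log-normal amplitudes around 0.3 µS),
the amplitude of a per-subject oscillation at a fixed random frequency in
0.08–0.24 Hz (0.12 µS per arousal unit), a tonic ramp during stimulation,
and an HR elevation (4 bpm per unit) through a 3 s first-order lag on top
of base HR (70 ± 6 bpm between subjects) and 0.25 Hz respiratory sinus
modulation. Anticipation arousal is 0.6 × the even blend of the upcoming
stimulus and the previous trial's realized arousal, which is what makes
previous-trial labels learnable from anticipation windows. VAS responses
are clipped rounded linear functions — pain of the trial's own arousal
(slope 2.2), anxiety of the previous trial's arousal (slope 2.0), noise
σ = 0.7 — so the anxiety/previous-pain association holds by construction
(measured r ≈ 0.9 at 40 subjects).

What the generator does **not** emulate: motion artifacts and
electrode-contact dropouts, habituation/sensitization across trials,
thermoregulatory baseline trends beyond a random walk, baroreflex
dynamics, PPG morphology variation, and realistic VAS responses biases.
Passing tests therefore demonstrate the pipeline's correctness and its
power under clean, controllable effect sizes — not expected performance on
human recordings, whose effect sizes are unknown here.

One structural property deserves emphasis: because the trial order is
fixed (as in the emulated protocol), stimulation level is confounded with
elapsed time. An "equal-gains" cohort is consequently *not* a null for
level classification — the accumulated tonic ramp makes time, and hence
the level schedule, learnable (measured AUC ≈ 0.69). Null calibration
therefore uses within-subject label permutation, which empirically centers
pooled LOSO AUC at 0.50. The spread of that null (s.d. ≈ 0.08–0.095
across permutation seeds) is dominated by the small evaluation size — 120
pooled predictions clustered in 20 subject folds — and sits above the
≈ 0.056 independent-sample floor; narrow tolerance bands on single-run
null AUCs at this cohort size are statistically unreliable, and the
acceptance checks report the measured in-band fraction rather than
pretending otherwise.

## Problem sizes used

Tests and the acceptance script run on sizes chosen to exercise every
code path at desk scale: 1000-case formula-oracle sweeps, 100 synthetic
decomposition recordings (60 s each), a 20-subject strong-effect cohort
for LOSO power, 20 permutation seeds for the null, a 40-subject cohort
for the label-structure correlation, and a 6-subject cohort for the
bitwise determinism round-trip.
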