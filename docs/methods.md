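# Methods

## Scope and model

`cyclesense` studies how nightly physiology tracks the menstrual cycle and
how far day-level fertile-window and menstruation membership can be
predicted from trailing wearable data alone. It covers five stages: a
synthetic cohort generator, preprocessing, a mixed-model phase analysis, a
day-level probability model over biphasic waveform features, and
participant-grouped evaluation. Everything operates on two plain-CSV tables:
nightly records (BBT in °C, nightly HR in bpm, SDNN in ms, LF/HF ratio,
menses and sync flags) and cycle annotations (onset date, length, menses
duration, ovulation day).

## Phase labeling

Day-of-cycle is 1-based; a cycle spans the first day of one menses up to the
day before the next. Days 1..menses_duration are MENSTRUAL. The fertile
window is the five days before ovulation plus the ovulation day. FOLLICULAR
is the remainder between menses and the window; post-ovulation days are
LUTEAL. When a short cycle overlaps menses with the window, precedence is
MENSTRUAL > FERTILE > FOLLICULAR: menses is directly observed, and the
follicular phase is *defined* as the leftover outside both. Cycles without a
determined ovulation day cannot be labeled and are excluded (a
`LabelingError` says so).

## Synthetic cohort generator

The generator emulates a two-group wearable cohort: 89 regular and 25
irregular menstruators, each followed for 3–4 contiguous cycles.

**Cycle structure.** Cycle lengths are drawn from discrete pmfs calibrated
so the lower-nearest inverse-CDF quartiles hit the study targets: regular
median 29 d (IQR 28–32) on support 25–35; irregular median 33 d (IQR 27–40)
on support 20–50. `calibrate_length_pmf` builds these by spreading mass
uniformly within quartile segments and placing a jump at each quartile that
leaves a 0.02 cumulative margin past the quantile level; the construction is
verified by an exhaustive cumulative-sum check before use. The margin
matters: a pmf whose CDF equals exactly 0.50 at the median makes any
draw-based median estimate a coin flip, whereas a 0.02 margin is ~4 binomial
SEs at 10,000 draws. Menses duration has median 6 d (IQR 5–7) on {4..8}.
Ovulation is luteal-anchored: ovulation day = length − luteal length, with
luteal length truncated-normal (mean 13.6 d, sd 1.2, bounds 11–16) — the
standard physiological account in which cycle-length variability lives in
the follicular phase, so long irregular cycles get long follicular phases.

**Nightly signals.** Each signal s on day d is

    y = mu_s + beta_s[phase(d)] + u_participant + v_cycle + shape_s(d) + eps

with Gaussian random intercepts at the participant and cycle level and
nightly Gaussian noise. Population means (BBT 36.63 °C, HR 62.50 bpm,
ln SDNN 4.80, ln LF/HF −0.55) and the phase effects (menstrual reference;
e.g. luteal BBT +0.19 °C, luteal HR +2.69 bpm) are literature-reported
mixed-model estimates for regularly cycling women and are the package's
defaults. SDNN and LF/HF are
generated on the natural-log scale and exponentiated. Variance-component
defaults (participant 0.15 °C / 4.0 bpm / 0.15 / 0.15; cycle 0.05 / 1.0 /
0.05 / 0.05; night 0.12 / 1.5 / 0.20 / 0.20) are our choices: only
fixed-effect SEs are published, so the components are set to make recovery
nontrivial but achievable at the cohort's size. Two waveform shapes keep the
biphasic transition realistic rather than an exact step: a 0.05 °C BBT nadir
on the day before ovulation, and a 2-day logistic ramp that replaces the
fertile-to-luteal BBT/HR step (weights ≈ 0.27, 0.73 on luteal days 1–2).
Both are on by default and removable. The ramp slightly attenuates the
*fitted* luteal contrast relative to the generating step (by roughly
step/luteal-length, ≈ 0.013 °C for BBT), which is visible in the
parameter-recovery numbers and well inside their tolerances.

**Missingness.** Independently per night, the wearable fails to sync with
probability 0.05 (clearing HR/SDNN/LF-HF) and the thermometer reading is
absent with probability 0.07. Menses self-report is never missing.

**What the generator does not emulate.** Real BBT/HR waveforms have
autocorrelated night-to-night noise, behavioral artifacts (alcohol, illness,
late nights), device drift, and non-Gaussian tails; missingness is not
independent of behavior. Passing tests on this generator shows the pipeline
recovers the assumed additive phase structure and that the predictive
stages behave correctly — not that real-world accuracy matches.

## Preprocessing

Intranight HR traces are summarized by the mean after trimming the first
and last 30 min; a night counts only when continuous sleep exceeds 4 h
(240 min, strict). Daily gaps are imputed by the mean of available values at
offsets −2, −1, +1, +2 days, in a single pass: previously imputed values are
never donors, so imputation is idempotent (given its own mask) and never
chains across a long gap. SDNN and LF/HF are natural-log transformed (raw
values must be positive). A cycle qualifies when synced wearable nights
cover at least 80% of its days (inclusive) and its ovulation day is known;
a night with BBT but no wearable sync counts as unsynced for completeness.
Waveform smoothing is a centered moving average truncated at boundaries
(default window 5 d, odd), exposed as a cross-validated hyperparameter.

## Phase analysis

Each signal is fit by REML with phase as the fixed effect and nested random
intercepts (participant, and cycle within participant) via statsmodels
MixedLM, qualified cycles only. The five reported contrasts
(follicular/fertile/luteal vs menstrual, fertile vs follicular, luteal vs
fertile) are Wald tests computed from the fixed-effect covariance of a
single fit — numerically identical to refitting with a different reference
— with Bonferroni adjustment, family size m = 5 by default (the printed
contrast family; m is a parameter). Group comparisons (irregular vs regular)
refit the same random structure within one phase with group as the fixed
effect. Residual diagnostics (summaries plus the D'Agostino–Pearson omnibus
test on conditional residuals) are descriptive only; the log transforms are
fixed policy, never gated on a test. The optimizer is L-BFGS with a Powell
retry; a singular fit reports the zero variance component with a warning
rather than failing.

## Day-level prediction

**Features.** To classify day t, only data strictly before t is used. The
trailing window (last W days, default 14, truncated to available history;
minimum history 7 d) is smoothed, then per signal (BBT and HR always; the
ln-SDNN and ln-LF/HF channels default ON for the fertile target, where
cross-validation shows a small consistent gain, and OFF for menses): the
last-3-day mean minus the window baseline, the z-scored last value, the
detected switch point's signed step and recency, and the least-squares
slope over the last 5 days. The last-value z-score uses the *raw* last
observation against the raw window — smoothing would dilute one-day events,
and the pre-ovulatory BBT nadir is exactly such an event. `detect_switch_point`
maximizes |post-segment mean − pre-segment mean| over all splits with at
least `min_segment` (default 2) days on each side, ties broken toward the
latest split. A calendar feature (days since last menses onset, capped at
60 when no onset is visible) is ON for the menses target and OFF for the
fertile target, keeping fertile prediction physiology-driven. A completeness
fraction (non-imputed share of the window) closes the vector; feature order
is fixed and versioned. Days whose window retains missing values after
imputation are excluded rather than guessed.

**Model.** An L2-regularized logistic regression over the standardized
features, with balanced class weights (positives are ~20% of days, and the
balanced loss puts the default 0.5 threshold at a sensible operating point).
Hyperparameters — trailing window W ∈ {7, 10, 14}, smoothing window ∈
{3, 5}, and the inverse-regularization strength over a log grid — are
chosen by participant-grouped fivefold cross-validation maximizing mean
validation AUC; folds are split by participant so no individual contributes
days to both training and validation. The winner is refit on all training
data. Standardization constants always come from the training folds. The
decision threshold is 0.5, inclusive. Models serialize to JSON with the
versioned feature order.

**What the linear score can and cannot express.** Fertile days are
*intermediate* on the elevation axis — above follicular, below luteal — so
a single linear score cannot rank them above both neighbors from elevation
alone; discrimination of fertile vs luteal/menstrual days rides on the
switch features, while fertile vs follicular rests on the mild pre-ovulatory
HR rise. This bounds the pooled day-level AUC on the synthetic cohort well
below what a calendar-aware model achieves, and is the main known
limitation of the physiology-only fertile model.

## Evaluation

The regular group is split at the participant level, 68 training / 21 test,
uniformly at random per seed; irregular participants are always test-only
and are scored with the regular-trained model. Metrics are day-level pooled
across all labeled days of qualified cycles: confusion counts, accuracy,
sensitivity, specificity at the threshold, and ROC/AUC by threshold sweep
with trapezoidal integration (equal to the Mann–Whitney concordance with
ties counted ½, which the test suite checks against a brute-force pairwise
oracle). One-class strata report the undefined entry as NaN with a flag,
never silently 0. Subgroup breakdowns stratify by cycle length (<25, 25–35,
>35 d). `run_pipeline` derives all stage seeds (generation, split, solver)
from one master seed, so runs are byte-identical.

## Numerical and design choices

- Quantile convention is lower-nearest inverse CDF everywhere (pmf
  calibration, empirical medians).
- The 80% completeness rule is inclusive (≥ 0.80).
- Imputation reads "two days before and after" as the four offsets
  ±1, ±2 days.
- The smoothing method is a boundary-truncated centered moving average; the
  source text leaves the method open, and a moving average keeps the
  switch-point arithmetic transparent.
- Switch-point ties break toward the latest admissible split so a flat
  series reports the most recent candidate.
- Degenerate inputs: single-class labels, one-group comparisons, absent
  reference phases, and infeasible quantile targets raise informative
  errors; non-convergence of the mixed model is flagged on the result, not
  raised.

## Problem sizes used in the checks

Parameter-recovery runs use the full default regular cohort (89
participants, 3–4 cycles each, ≈ 9,300 nightly records per replicate)
averaged over five seeds. Generator-calibration checks draw 10,000 cycle
lengths per group. The end-to-end prediction check runs the full default
two-group cohort once; the signal-ablation (chance-level) check uses a
50-participant regular cohort with all phase effects and waveform shapes
zeroed and a single hyperparameter point, which keeps the null AUC's
sampling noise small while exercising the whole pipeline.
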