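# Methods

`afpulse` rebuilds, on synthetic data, the validation of continuous
PPG-based 1-minute mean heart-rate (HR) assessment during persistent
atrial fibrillation (AF) against simultaneous Holter ECG: the signal
processing chain, the quality-gated HR rule, minute-level agreement
statistics, stratified accuracy analyses, and four correction models
compared under 5-fold cross-validation. No patient data are used;
everything downstream of the generator is testable against known ground
truth.

## The synthetic cohort

Each simulated patient carries three time-locked streams over 24 h
(configurable): reference ECG beat times, a 25 Hz multi-channel PPG
waveform, and a 50 Hz 3-axis accelerometer trace, anchored to local
wall-clock time (recordings start at 12:00).

**AF rhythm.** RR intervals are independent log-normal draws, clipped to
[0.25, 4.0] s, with separate day and night means (defaults 0.75 s /
0.92 s, per-patient jitter of ~8%) switched on a 23:00–07:00 sleep
schedule. Serial independence is a deliberate simplification of AF's
irregularly irregular rhythm; it yields lag-1 interval autocorrelation
near zero. Because intervals are iid, RMSSD = √2·SD(RR), so the default
interval SD of 0.184 s reproduces the cohort-median RMSSD of 0.26 s
exactly in expectation (the printed unit "ms" for that median is
physically implausible for beat intervals and is read as seconds).

**Pulse deficit.** Each beat contributes a pulse template (systolic peak
plus dicrotic bump) at beat time + 0.25 s transit delay, scaled by the
diastolic filling law

    A_i = A_max · (1 − exp(−RR_{i−1}/τ)),

so short preceding diastole produces a weak peripheral pulse. τ
(default 0.30 s) is the filling time constant; *larger* τ means slower
refilling and a stronger deficit. Weak pulses can fall below the beat
detector's adaptive threshold, and closely spaced pulses can merge
after smoothing, so the PPG HR underestimates truth at fast rates —
the mechanism behind the poor >110 bpm agreement in the emulated
analysis.

**Motion and artefacts.** At rest the accelerometer reads exactly
(0, 0, 9.81) m/s²; minute-mean vector magnitudes therefore start at
gravity and rise with activity, spanning ≈9.8–10.1 m/s² as in
wrist-worn recordings. Waking minutes carry low-level ambient motion
(intensity |N(0.10, 0.07)| m/s²) plus Poisson bursts (6/h, 10–600 s,
0.1–0.6 m/s²); nights are nearly still. The same intensity envelope
drives broadband PPG noise (1.5 × intensity above a 0.05 m/s² deadband),
coupling motion to signal corruption exactly where the accelerometer
sees it.

**Dropouts and pathology.** A fraction of minutes (default 0.32) has
its PPG replaced by pure noise, modelling device-side quality dropouts;
together with motion-driven rejections this yields ≈40% total PPG
insufficiency — the emulated study's accounting (60% of minutes
analyzable). The true quality label is retained so gate recall is
testable. 26% of patients get chronic-heart-failure pulse morphology:
damped (×0.8), broadened (×1.35) templates with beat-to-beat amplitude
jitter (log-SD 0.25), degrading — but not categorically breaking —
beat detection. A small ECG dropout fraction (0.002) exercises the
four-way exclusion accounting.

## The measurement chain

1. **Preprocessing** (per channel): linear interpolation to 30 Hz,
   centred moving average, Savitzky–Golay smoothing (order 3), first
   derivative, z-normalization. Windows are 120 ms (moving average) and
   250 ms (Savitzky–Golay). Wider windows (150/350 ms) were rejected
   during design because they merge beats ~0.3 s apart — common in fast
   AF — which breaks minute-HR fidelity below 110 bpm; the final
   windows keep artefact-free minute HR within 2 bpm of truth across
   40–110 bpm while preserving the deficit-driven underestimation above
   110 bpm.
2. **Quality annotation.** The original device classifies signal spans
   with a proprietary recurrent network; this package substitutes a
   declared rule-based index. 8 s windows (hop 4 s) are scored by
   beat-shape stability (mean correlation of per-beat epochs with their
   average shape), autocorrelation peak prominence in the physiologic
   interval band 0.25–3 s (weight 0.1), minus an accelerometer
   burst-power penalty (0.3 × mean |magnitude − g|). Windows below the
   0.95 threshold are insufficient; labels are merged into spans tiling
   the minute. The threshold is an operating point fixed against the
   generator's designed extremes (clean pulse ≈ 1.0, pure noise ≈ 0.9);
   it is configuration, not a learned quantity.
3. **Beat detection:** local maxima of the derivative signal with a
   0.25 s refractory period and an adaptive height threshold (0.40 × the
   95th percentile of positive samples), restricted to sufficient
   spans. The adaptive threshold is what lets weak (deficit) pulses go
   undetected, as intended.
4. **Minute HR:** intervals are formed only between consecutive beats
   inside one sufficient span; if at least 20 such intervals exist,
   HR = 60 / mean(interval), constrained to the device range
   [20, 250] bpm; otherwise the minute is "insufficient". The emulated
   study describes the cutoff both as at least 20 beat-to-beat
   intervals and as at least 20 heartbeats (20 beats = 19 intervals);
   the stricter ≥20-intervals reading is the default and the cutoff is
   a config key. With several
   PPG channels, the best channel per minute (by sufficiency, then
   quality fraction) is used.

## Segmentation and strata

Minutes are cut on wall-clock boundaries. Reference HR is 60 / mean of
the ECG intervals fully inside the minute. Motion covariates are the
mean and SD of the accelerometer vector magnitude over the minute.
Day is 08:00–22:00, night 00:00–06:00; transition hours are excluded
from the day/night contrast. Motion quartiles G1–G4 use either the
published fixed boundaries (9.85/9.92/10.04 m/s², implemented as
half-open real intervals) or empirical quartiles of the included
segments (default). A minute is included iff both modalities produced
an HR; exclusions are counted as ECG-only / PPG-only / both.

## Agreement statistics

RMSE = √(mean (HR_PPG − HR_ECG)²); Bland–Altman bias ± 1.96·SD of the
differences (sample SD, ddof = 1, switchable); accuracy = % of pairs
deviating strictly less than ±10% of the ECG value (a deviation of
exactly 10% is inaccurate). Rate-control categories are ≤80,
(80, 110], >110 bpm — half-open so 80 and 110 belong unambiguously —
with a ≤40 bpm sub-band flag. Fisher's exact two-sided P is computed by
exact integer hypergeometric enumeration, summing all tables with
point probability ≤ the observed one; `scipy.stats.fisher_exact` serves
as an independent oracle in the tests only. Day-vs-night and G1-vs-G4
accuracy contrasts report both the naive Fisher test (segments treated
as independent) and a per-patient clustered paired check, since
within-patient clustering makes the naive test anticonservative.
Per-patient summaries flag an agreement rate < 95% as "low agreement";
the cohort's low/high split is compared on clinical covariates with
the same Fisher machinery.

## Correction models

All models map the five watch-derived minute features (PPG HR, RMSSD,
quality fraction, motion index, motion SD) to the reference HR:

* **A (naive):** the PPG HR at face value; no fitting.
* **B (linear):** OLS with intercept (ridge fallback on rank-deficient
  designs).
* **C (MLP):** 5→10→10→1 feed-forward net (ReLU, Adam, MSE), via
  scikit-learn, features and target standardized on training folds.
* **D (LSTM):** windows of the current minute plus up to nine
  preceding minutes with a missing-minute mask; two parallel paths
  (path 1: HR + RMSSD; path 2: quality + motion features — the split
  is not specified in the emulated study and is a design choice), each four
  stacked LSTM layers of five units and a dense layer of eight,
  concatenated into one linear output. Implemented in numpy with full
  backpropagation through time, Adam, and global-norm gradient
  clipping; masked steps carry the recurrent state through unchanged.
  Training is deterministic under a fixed seed.

Models B–D are evaluated with k-fold cross-validation (default 5
folds). Folds group by patient to prevent within-patient leakage (the
emulated study does not state its grouping; by-segment mode exists for
comparison). Model A is evaluated on the identical pooled out-of-fold
set without fitting. The 95% CI is a t-interval over the five fold
RMSEs (the emulated study's CI method is unstated). Unstated training
hyperparameters (ReLU-class activations, Adam, epochs, batch 256) are
fixed in configuration with seeds.

## What the synthetic data do and do not show

The generator reproduces the *structure* the analysis depends on —
AF-scale interval variability, rate-dependent pulse deficit,
motion-coupled artefacts, quality dropouts, day/night activity — so
passing tests demonstrate that the measurement chain, gating rules,
statistics and models behave correctly under that structure. It does
not emulate pulse-transit-time variability, respiratory modulation,
sensor quantization, baseline drift of real optical sensors, rhythm
transitions, or ectopy. Night-time minutes are consequently cleaner
than real recordings (RMSE well below the published 2.8 bpm), and
absolute error levels in general are smaller than in the study; the
reproduction targets are orderings and mechanisms (night better than
day, accuracy falling with motion, underestimation above 110 bpm, no
correctable systematic bias), plus the exact arithmetic reproductions
computed from the published count tables.

## Numerical choices and degenerate inputs

All-constant PPG segments normalize to zero and are flagged degenerate
(whole minute insufficient). Empty strata are omitted with a warning;
degenerate Fisher margins return P = 1 (with a small relative tolerance
against floating-point ties in the enumeration). Minute HR outside the
device range [20, 250] bpm is treated as insufficient. Quartile and
rate-category boundaries are half-open to avoid gaps and overlaps.
Clock skew between devices is assumed zero in simulation.

## Problem sizes

Test and acceptance runs use scaled-down cohorts chosen as this
package's own defaults for desk-scale reproduction: 3–8 patients ×
24 h for waveform-level pipelines (several thousand analyzable
minutes), segment-level scenario tables of 6–10 patients × 100–200
minutes for the correction-model experiments, and 20 seeded replicates
for the no-improvement null check. The published cohort (50 patients,
~79k simultaneous minutes) is emulated in structure, not in size.
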