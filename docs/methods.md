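# Methods

## Overview

`bcgfatigue` implements a quantitative mental-fatigue evaluation pipeline
built on ballistocardiogram (BCG) signals. A BCG records the small recoil
of the body to each cardiac ejection; an unobtrusive seat sensor can
acquire it without skin contact. The pipeline has five stages:

1. **Synthetic BCG generation** with known ground truth (`synthetic`);
2. **Spectral heart-rate estimation** in the cardiac band (`spectral`);
3. the **HRV index** `V = (h_ref / h)^4` (`hrv`);
4. **reference-vs-window random-forest classification** (`classify`);
5. **agreement and correlation statistics** (`evaluation`),

orchestrated end to end by `pipeline`/`cli` and by the numbered drivers
under `analysis/`.

## Synthetic BCG model

One beat is a sum of eight signed Gaussian bumps at fixed fractions of
the cardiac cycle, following the canonical G, H, I, J, K, L, M, N wave
morphology: positive H/J/L/N deflections, negative I/K/M troughs, and the
J peak dominant. Published BCG descriptions fix only the wave order and
the dominance of J, not amplitudes or timings, so the defaults were tuned
once by eye to the canonical morphology and are fully configurable.

One constraint is structural rather than cosmetic: because offsets and
widths are cycle fractions, the harmonic envelope of a periodic beat
train is a property of the template alone. The default template keeps the
fundamental Fourier coefficient strictly larger than every harmonic
(`BeatTemplate.fundamental_dominance() ≈ 1.74`), which is what makes the
power-spectrum peak of the filtered train sit at the beat frequency for
any heart rate in the 30–150 beats/min band. Narrower waves would hand
the spectral peak to a harmonic and break frequency-domain heart-rate
readout — for spikier real sensors that failure mode is real and the
estimator would need harmonic disambiguation.

Beat timing follows an instantaneous trajectory

    HR(t) = baseline_hr * (1 − drift_fraction * t / duration)

with independent Gaussian beat-to-beat jitter (`hr_jitter_sd`), clipped
to the 40–180 beats/min sensor operating range. The linear decline is the
minimal model exposing a monotone fatigue trend; it emulates the
literature finding that heart rate falls as mental fatigue deepens, and
`drift_fraction` (default 0.10 over a 120-min task) is the single
"fatigue effect size" dial. Respiration is a single sinusoid (default
0.25 Hz, amplitude 0.3 relative to the J peak) deliberately placed below
the 0.5 Hz passband edge so the band-pass filter is tested by something
it must actually remove; sensor noise is white Gaussian (default sd 0.1).

Ground truth is stored two ways: realised J-peak times (with jitter), and
the **noise-free trend** `HR(t)` at 1 Hz in `truth_hr`. Estimator error
is scored against the trend, so jitter is treated as physiological noise
around the quantity of interest, not as signal to recover.

Cohort defaults mirror the study layout: 20 subjects, 7200 s at 10 Hz.
Per-subject profiles draw baseline heart rate uniformly on 62–88
beats/min and respiration on 0.20–0.30 Hz — plausible seated young-adult
ranges — with jitter sd 2.5 beats/min, a value that puts per-second
heart-rate spread at the same scale as the per-window drift so that early
windows genuinely overlap the reference state (as the published accuracy
trend, rising from ~72 % rather than starting saturated, implies).
Subject seeds derive from one master seed via `SeedSequence`, so any
subject regenerates in isolation and the whole cohort is bitwise
reproducible.

Not modelled: sensor optics, movement artifacts, arrhythmias, non-linear
HR dynamics, respiratory sinus arrhythmia coupling. Passing tests
therefore show the *method* behaves correctly when its assumptions hold,
not that real recordings meet those assumptions.

## Heart-rate estimation

The signal is filtered with a second-order Butterworth band-pass,
0.5–2.5 Hz (30–150 beats/min). Filtering is zero-phase
(forward–backward, `sosfiltfilt`) by default since the analysis is
offline; a causal mode is kept because a real-time sensor is causal.
Heart rate is the power-spectrum peak frequency × 60.

Unstated implementation choices, made here explicitly:

- **Window**: 10-s trailing window per emitted second — the shortest
  window holding ≥ 5 cardiac cycles at the 30 beats/min band edge. The
  first seconds are backfilled from the first complete window.
- **Resolution**: raw bins of a 10-s window are 0.1 Hz = 6 beats/min, so
  segments are zero-padded 8× and the peak refined by parabolic
  interpolation over the three bins around the argmax, giving sub-bpm
  precision (needed for beats/min-level agreement).
- **Taper**: Hann, to suppress leakage. **Ties**: argmax takes the lowest
  frequency. Peak search is restricted to the passband, so every
  estimate lies in [30, 150] by construction; a peak-to-median band
  power ratio is available as a confidence flag for noise-only segments.

Measured performance on the default synthetic cohort: mean per-second
|estimate − trend| ≈ 0.8 beats/min; on noiseless constant-rate records
the error is < 0.05 beats/min across 45–150 beats/min.

## HRV index

`V = (h_ref / h)^4`, where `h_ref` is the subject's mean heart rate over
the first 10 min (the non-fatigued reference state). V is dimensionless,
equals 1 at the reference, is strictly decreasing in `h` and invariant to
common rescaling; the fourth power amplifies small heart-rate declines.
V is computed over the reference window as well — those seconds are the
reference-state samples for classification and fluctuate around 1 (the
Jensen gap of the fourth power is < 1 % at realistic jitter). No
smoothing is applied.

## Classification protocol

One sample per subject-second of the HRV series. Pooled across the
default 20 subjects, the 600 reference seconds give 12,000 reference
samples; each later 10-min window contributes 12,000 candidate-state
samples (window k = minutes 10k–10(k+1), k = 1..11 for 120 min). The
per-sample feature is the scalar V by default; `feature_lags` optionally
appends the preceding seconds (blocks pad their first seconds by
repetition), which also makes the forest's d-of-D feature subsampling
non-degenerate (d defaults to ⌈√D⌉).

Each window is scored by repeated hold-out: a stratified random 80/20
train/validation split, a 100-tree random forest (unlimited depth,
majority vote), accuracy on the held-out 20 %, repeated 20 times with
independent splits and averaged. Stratification and pooling across
subjects are this package's explicit choices; the protocol description
they implement leaves both unstated. Splits ignore subject identity,
which inflates absolute accuracy relative to a leave-subject-out design —
acceptable here because the quantity of interest is the per-window
*trend*, not a deployable classifier.

Under the null (no drift) the two classes are exchangeable and measured
accuracy sits at 50 % (observed 49.8–52 % per window); with the default
10 % drift, accuracy rises monotonically from ~55 % in the first window
to ~100 % in the last, and the Pearson correlation between per-window
mean V and mean accuracy is ~0.85–0.90 across cohort seeds. The
published real-data analogs (72.3→96.5 % accuracy, r = 0.98) are
qualitative targets only: the real recordings were never deposited, so
trend direction and correlation strength — not their exact values — are
the reproducible content.

## Agreement statistics

The packaged fixture ships the 20 paired sensor-vs-monitor heart-rate
readings verbatim. Their absolute errors give mean 1.30 beats/min and
maximum 3 beats/min exactly. The dispersion of those errors is 0.81 as a
*population variance*, 0.90 as a population standard deviation and 0.92
as a sample standard deviation; the report exposes all three rather than
picking the one that matches any particular published "±" figure, since
the provenance of such figures is often unstated.

Correlation between per-window mean HRV and accuracy is Pearson's r (a
linear relationship is the claim being checked); both vectors are also
min–max normalised to [0, 1] for plotting on a common scale, which leaves
r unchanged (affine invariance, asserted to 1e−12 in tests).

## Numerical and degenerate-input policy

- All randomness flows from explicit integer seeds; identical inputs give
  bitwise-identical outputs (filter, FFT and forest are deterministic
  given seeds).
- Constant segments raise a "no cardiac signal" error rather than
  returning an arbitrary in-band value; constant vectors make min–max
  normalisation and correlation raise rather than emit NaN.
- Heart rates ≤ 0 are rejected before the fourth-power ratio.
- Config invariants surface as data (`validate_config` returns messages)
  before any pipeline stage runs; library entry points raise on the same
  violations.

## Problem sizes used in tests and the acceptance script

The full study scale (20 subjects × 120 min, 11 windows × 20 repeats) is
used wherever a claim depends on it (the 12,000-sample count, cohort
heart-rate recovery, and the full drifting-cohort analysis in
`scripts/acceptance.py`). Two checks run at reduced scale as a deliberate
choice, because their conclusions are size-independent while repeated
forest fits on 24,000-sample datasets dominate runtime: the chance-level
null uses 8 subjects × 60 min (20 repeats kept), and the multi-seed trend
check uses 10 cohorts of 8 subjects × 120 min with 3 repeats each. The
trend assertions (monotone HRV, positive accuracy trend, r > 0.8) hold at
both scales.

## Known limitations

- The generator's fatigue model is a deterministic linear trend; real
  fatigue onset is nonlinear and subject-specific (the published accuracy
  even dips in the final 10 min, which a linear model cannot produce).
- Spectral readout assumes a fundamental-dominant beat template; spiky
  morphologies would require harmonic disambiguation.
- Pooled splitting measures state separation, not subject-generalising
  classification.
- Absolute V values depend on jitter scale and estimator smoothing, so
  only trends and correlations transfer across generator settings.
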