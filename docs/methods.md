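# Methods

## Problem and pipeline

The package implements an EEG screening analysis for fetal alcohol spectrum
disorders (FASD): given ~1 minute of 18-channel bipolar ("double banana")
scalp EEG per child, decide whether the recording belongs to the FASD or
the control class.  The pipeline is

1. **Acquisition-matching preprocessing** — a zero-phase 50 Hz notch
   (second-order IIR, 2 Hz bandwidth, Q = 25) removes mains interference.
2. **Band decomposition** — each channel is split into the five clinical
   bands with zero-phase 4th-order Butterworth band-passes:
   delta 0.5–4, theta 4–7, alpha 7–12, beta 12–30, gamma 30–45 Hz.
   Alpha is fixed at 7–12 Hz because the class effect of interest is an
   alpha-power deficit; the other edges are conventional choices and
   configurable.  Gamma stops at 45 Hz to stay clear of the notch.
3. **Feature extraction** — ten time-domain statistics per (channel, band)
   signal: RMS, skewness, kurtosis (raw, Gaussian → 3), crest factor
   (max|x|/RMS), peak-to-peak, power of the upper and of the lower
   envelope, signal power (mean x², identically RMS²), minimum, maximum.
   With 18 channels × 5 bands × 10 features this yields one 900-value
   study vector per subject, ordered channel-major, then band, then
   feature.
4. **Classification** — Gaussian naive Bayes written from Bayes' theorem:

       P(c | x₁…x_n) ∝ P(c) ∏ᵢ N(xᵢ; μ_{c,i}, σ²_{c,i})

   with priors from class frequencies and per-class/per-feature means and
   population variances.  Prediction is argmax of the log posterior.
5. **Evaluation** — repeated random subsampling: 30 train + 20 test per
   class, drawn stratified without replacement, 1000 shuffled trials;
   mean accuracy, SD over trials, and a confusion matrix normalised per
   true class (TP+FN = 100 over the FASD class, TN+FP = 100 over
   controls) pooled by summing counts over trials.  Stratified 4-fold CV
   is reported alongside as a secondary figure; the two protocols are
   never merged into one number.

## Synthetic cohort generator

Clinical FASD recordings are not publicly available, so every experiment
runs on a synthetic cohort built to carry the same statistical structure
the analysis assumes:

* **Background**: Gaussian noise with power spectral density ∝ 1/f^β
  (β = 1 by default), produced by frequency-domain shaping of white noise
  with the DC bin zeroed and weights normalised so expected per-channel
  variance is exactly 1, then scaled to `background_rms` (default 5 µV).
* **Band oscillations**: independent white noise passed through the same
  Butterworth band-passes as the analysis, rescaled channel-wise to an
  exact target variance.  Defaults (µV²): delta 25, theta 9, alpha 16,
  beta 4, gamma 1 — low-frequency-dominant, as in paediatric resting EEG.
* **Class effect**: the FASD alpha variance is multiplied by
  `1 − alpha_reduction` (default 0.3).  All other bands are identical
  across classes.
* **Blink artifacts**: positive 300 ms squared-sine transients of
  `blink_amplitude` (default 100 µV) at Poisson-distributed times, only on
  channels containing "Fp"; default rates 2/min (control) vs 6/min (FASD),
  reflecting the more frequent ocular artifacts seen in the study class.
  No ocular dipole or volume conduction is modelled.
* **Between-subject variability**: each subject draws one log-normal,
  unit-mean power multiplier per band (σ = 0.35), shared by all channels
  of that band, plus independent per-channel log-normal jitter (σ = 0.2).
  Without this, subjects of a class would be statistically identical and
  classification would be trivially perfect.

Every operation takes an explicit seed; a cohort is bit-reproducible from
`SimConfig.seed`, with per-subject streams spawned from a seed sequence.
Default duration is 60 s per subject (the clinical recordings are ~15 min;
1 minute keeps the whole study desk-scale while leaving band-power
estimates well converged — relative SE of alpha power over 60 s is a few
percent).  Default cohort size is 50 + 50, matching the study design.

What the generator deliberately does **not** emulate: non-stationarity
(drowsiness, photostimulation and hyperventilation responses), non-blink
artifacts (muscle, electrode pops), inter-channel correlation from volume
conduction, and any topographic structure of the alpha deficit.  Passing
tests therefore show that the pipeline recovers the class structure it is
pointed at — not that real FASD EEG is classifiable at any particular
accuracy.

## Numerical choices

* All filtering is forward–backward (`sosfiltfilt`/`filtfilt`), so the
  moment-based features see no phase distortion; the effective magnitude
  response is the square of the design response.
* Envelopes are cubic splines through strict local maxima (upper) and
  minima (lower) with the endpoints included as knots.  This yields
  genuinely distinct upper/lower envelopes for asymmetric signals, which
  the analytic-signal magnitude cannot.  Splines may cross between sparse
  extrema; that is accepted.  Signals with fewer than two interior maxima
  or minima, and constant signals, raise a degenerate-signal error that
  names the offending channel and band.
* Moments are population moments (no bias correction); kurtosis is raw,
  not excess.  "Signal power" equals RMS² by identity; both are emitted
  because the study's feature list names both.
* Naive Bayes scoring is strictly log-domain (a 900-term likelihood
  product underflows doubles).  Variances are clamped from below by a
  relative floor, 1e-9 × the largest per-feature variance across classes,
  because feature scales span µV to µV⁴; an absolute smoothing constant
  would swamp the small-scale features.  Exact ties in the posterior
  resolve to the earlier class in fitting order (controls first in the
  standard cohort layout).
* Trial t of the subsampling protocol uses the random stream
  `seed + t`, making individual splits reproducible in isolation.
* EDF files are written with a single data record spanning the recording
  and a symmetric physical range just covering the signal, so 16-bit
  quantisation error is bounded by range/2¹⁶ per sample.  Reading goes
  through MNE; class labels live in a sidecar manifest CSV, never in the
  EDF header.

## Known limitations

* **Null-cohort offset.**  With exchangeable classes (no simulated
  effect), repeated 30/20 subsampling inside one fixed 50+50 cohort does
  *not* centre at 50% accuracy.  The classifier re-learns, trial after
  trial, whatever chance separation the cohort's two groups happen to
  have, biasing the 1000-trial mean upward; with many uninformative
  features a competing below-chance effect (train/test anticorrelation —
  the 30+20 split exhausts each class) pushes the other way.  Measured
  across independent null cohorts the 1000-trial mean accuracy is
  ≈ 0.515 with a cohort-to-cohort SD of ≈ 0.04.  A ±2-point band around
  50% is therefore a property of the cohort draw, not of the pipeline,
  and the null-calibration acceptance check can fail for an unlucky
  cohort while the pipeline is working exactly as designed.  The same
  caveat applies to the original study protocol itself.
* Accuracy on the default synthetic cohort depends on free generator
  parameters (effect size, subject variability) that the source data do
  not pin down quantitatively; the defaults are plausible, not fitted.
* The alpha deficit is simulated as spatially uniform; a focal deficit
  would engage fewer features and lower sensitivity.
* 4-fold CV on 100 subjects has high variance (four 25-subject folds);
  it is reported as a secondary check only.
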