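# Methods

This note records the models the toolkit implements, the defaults it
ships with and why, what the synthetic generators do and do not emulate,
and the numerical choices a maintainer would want to know.

## Radar forward model

The simulator implements a single-reflection FMCW model: the IF sample of
chirp l, fast-time sample k is

    y(k,l) = √P_R · β · exp(j(2π f_b k T_f + 4π R(l T_s)/λ + 2π d_m sinΘ/λ))

with f_b = (B/T_C)·2R̄/c held constant across chirps (R̄ = mean range of
the observation).  Chest motion is below a millimetre while a range bin
is 3.75 cm wide, so treating the fast-time tone as chirp-invariant is
physically exact to ~10⁻⁵ of a bin and makes the slow-time phase at the
selected FFT bin equal 4πR/λ + constant to machine precision — an
invariant the tests check at 1e−9 rad.

Waveform defaults: 77 GHz start frequency, 4 GHz sweep, 50 µs chirps,
2 Msps ADC (100 samples/chirp), 20 chirps/s slow axis, 512 chirps =
25.6 s per observation.  The range-bin width is derived as c/(2·bandwidth)
= 3.75 cm and follows the configured bandwidth.

Displacement model: R(t) = R₀ + g·(b·sin(2πf_b t) + h·p(2πf_h t)) +
rbm(t).  Breathing is sinusoidal (default 4 mm at 0.3 Hz, the mm-scale
excursion of a seated adult); the heartbeat pulse p is a raised cosine
occupying the first 20% of each period (default 0.3 mm at 1.2 Hz) — a
sharp pulse rather than a sinusoid so that downstream peak detection has
well-defined maxima, which is how measured heartbeat phase signals look.
Random body movement is an additive Hann-shaped displacement burst (smooth
onset/offset; the waveform of a real shift of posture is unknowable, and
a smooth bump avoids injecting synthetic step discontinuities).
`orientation_gain` ∈ (0,1] attenuates the vital displacement to emulate
off-axis orientations.  IF noise is additive complex Gaussian (default
off: residual phase noise is negligible at sub-1.5 m range because
transmit and receive share an oscillator), with an optional slow-time
phase random walk.

## Vitals DSP

Processing order: range FFT (one-sided, bins 0..n_fast/2) → bin selection
(argmax of time-averaged magnitude over bins ≥ 1, excluding DC; ties to
the smaller bin) → four-quadrant phase in (−π, π] (−π is mapped to +π) →
`numpy.unwrap` → band-pass → motion denoising → adaptive peak filtering →
rate estimation.

**Band-pass cascades.** Each band is a Butterworth band-pass realized as
serially cascaded biquad (second-order) sections.  Six sections (12th
order) are used per band: measured one octave outside the edges the
attenuation is −37.8/−42.3 dB (cardiac) and −30.1/−30.3 dB (breathing),
comfortably past the 20 dB the design targets, and — decisive for the
energy mask below — a 4 mm breathing excursion (≈13 rad of phase)
anywhere in 0.1–0.5 Hz leaks < 0.006 rad² of energy into the cardiac
band.  With only two sections the octave attenuation is ~15–19 dB and the
breathing leak alone rivals the motion threshold.

**Zero-phase default.** The pipeline applies the cascades
forward-backward (`sosfiltfilt`).  The causal mode (one flag away,
matching a live monitor) has frequency-dependent group delay near the
band edges that dephases the heartbeat pulse's in-band second harmonic
(e.g. 1.8 Hz when the heart beats at 0.9 Hz); dephased harmonics raise
spurious positive secondary maxima and can double the detected peak
count.  Zero-phase filtering keeps the harmonics aligned, so the
secondary extremum of cos θ + a·cos 2θ stays negative and is excluded by
the positivity rule.

**Motion denoising.** Window energy is the mean of squared samples
(rad²) over consecutive non-overlapping 1 s windows — length-invariant,
so the threshold does not depend on the window's sample count — with
windows above E_th = 0.04 rad² masked out of all downstream peak
detection.  The mask is computed once on the cardiac-band series and
applied to both bands.  Rationale: at λ ≈ 3.9 mm the *breathing-band*
phase of any physiological breath is tens of rad² and would always trip a
fixed threshold, whereas the clean cardiac band carries ~0.01–0.02 rad²
(heartbeat fundamental plus residual leakage) and an RBM burst carries
far more than 0.04 rad², so the threshold separates motion from vitals
exactly where it is calibrated.  A fixed threshold (rather than one
scaled to signal power) keeps the rule auditable: the tests verify window
by window that discards match the E_th rule.

**Adaptive peak filtering.** Candidates are strict local maxima with
positive amplitude inside retained windows, refined to sub-sample
precision by parabolic interpolation through the three samples around
each maximum (removing the 50 ms quantization of the 20 Hz slow axis,
which would otherwise bias high heart rates by >2 BPM).  Distances
between consecutive candidates in the same retained segment are pooled;
a peak whose preceding same-segment distance falls outside mean ±
max(SD, 1e−9 s) is rejected in a single pass (the earlier peak is kept;
when all distances are equal the SD floor keeps everything).  A peak that
opens a new retained segment has no preceding distance and is kept.

**Rate estimation.** 60 over the mean beat-to-beat interval.  In the
pipeline the averaged intervals are the *accepted distances* of the
filter: a diff across a rejected peak or a masked gap is the sum of two
or more physiological intervals and would bias the mean upward.  The
standalone `estimate_rate` keeps the simple 60/mean-diff contract.

**Heart-rate variability caveat.** The adaptive filter deliberately
discards rhythm outliers; arrhythmia screening therefore extracts its RR
intervals from the *unfiltered* candidate peaks (`raw_peak_intervals`,
0.3 s refractory) — otherwise the ectopic beats that carry the class
signal would be filtered away.

## QRS reconstruction

The triangular pulse f(t) = A(1 − B|t|/T) on |t| ≤ T/B has the cosine
series (b_n = 0 by evenness)

    a₀ = A/B,   a_n = (A·B)/(n²π²)·(1 − cos(2πn/B)),

derived by direct integration and verified against a 10⁶-point
trapezoid-rule oracle whose grid is split at the pulse's kinks (so each
segment integrates a smooth function).  The coefficients equal the
single-pulse integral even when B < 2 makes neighbouring pulses overlap
(at B = 1 the periodic summation is exactly the constant A, which the
closed form reproduces).  A legacy closed form
(a₀ = AB(2−B), a_n = (2BA/(n²π²))(1 − cos(nπ/B))) circulates in the
literature of this construction; it does not reproduce the pulse — at
B = 2 it assigns zero mean to a pulse of positive area — and is retained
in `printed_fourier_coefficients` for comparison only.

Synthesis: each inter-peak gap defines a local period T_i, one truncated
pulse is centred on each peak (segment boundaries at gap midpoints), the
train is generated at 100,000·n/duration Hz (n = peak count) and
decimated to 5 Hz — polyphase decimation by 10 while more than 30×
oversampled, then one Fourier-domain resample for the final non-integer
step.  Defaults: B = 8 (QRS support T/4, a plausible QRS fraction of a
beat), 32 harmonics (truncation error decreases monotonically as terms
double, which the tests assert), amplitude = mean detected peak value
(only timing carries information downstream).

Spectral statistics: the periodogram is the standard one-sided
mean-removed estimate (rectangular window, so Parseval holds exactly);
the headline argmax and the SNR use a Hann window because rectangular
sidelobe leakage of an off-bin fundamental can hand the argmax to a
harmonic nearer a bin centre.  SNR is the PSD mass within ±5 bins of the
fundamental and its second harmonic versus all remaining non-DC mass,
in dB.

## ECG toolkit

Normalization maps archival integer samples to mV via
(raw − baseline)/gain; the synthetic generator writes raw adu (gain 200,
baselines 0 or 1024, rates 128 or 360 Hz) so the quantization of the
archival format is exercised.  Artifact removal cascades 4th-order
Butterworth stages — low-pass 30 Hz (muscle tremor), band-stop 48–52 Hz
(mains), high-pass 0.8 Hz (baseline wander) — applied zero-phase to
preserve R-peak timing; a stage whose edge would reach Nyquist is skipped
with a logged warning.  R peaks: squared-derivative energy smoothed over
150 ms, thresholded at half its rolling 2 s maximum, 0.2 s refractory,
refined to the extremum of |ECG| within ±75 ms (hence robust to polarity
inversion).  The generator sums Gaussian bumps (P, Q, R, S, T) per beat
with offsets proportional to the local RR interval; it emulates beat
timing and gross morphology, not ST-segment or P-wave pathology, so
passing tests demonstrate timing-feature fidelity only.  A WFDB reader
exists behind an optional import for users with locally downloaded
records.

## RR features and classifier

Features: mean RR, (max−min)/mean, RMSSD with the published n−2
denominator (n = interval count; the conventional n−1 is a flag away;
with two intervals the published denominator vanishes and RMSSD is
reported as missing rather than fabricated), CoV with sample SD, and
normalized absolute deviation; plus age and gender (male = 1, female = 0).
Min–max scaling to [0,1] is fit on the training split only and travels
with the serialized model.

The classifier is an 8/16/1 sigmoid MLP on the 7 features (225
parameters; weights ~ Normal(0, 1/fan_in), zero biases).  Training is
full-batch Levenberg–Marquardt: Δ = −(JᵀJ + μI)⁻¹Jᵀr with the Jacobian
from backpropagation; a step is accepted only if training MSE decreases
(μ ×10 and retry otherwise, μ ÷10 on acceptance; μ₀ = 10⁻³; exceeding
μ = 10¹⁰ aborts with a convergence-failure stop reason).  One epoch = one
accepted step, 10 epochs by default, best-validation checkpointing with
patience 10 (ties keep the earlier epoch).  The 70/15/15 split uses
largest-remainder rounding within each class stratum (33 examples →
23/5/5).  Output threshold 0.5.

## Synthetic cohorts: what they emulate and what they don't

Normal subjects draw RR intervals with 3% multiplicative jitter
(CoV ≈ 0.03, resting sinus rhythm); arrhythmic subjects use 15% jitter
plus ectopic short/compensatory-long pairs at 15% incidence
(CoV ≳ 0.15), mean RR from U(0.7, 1.0) and U(0.6, 1.1) s respectively,
ages uniform over 20–83, both genders.  These classes are cleanly
separable in RR-variability space, so classifier accuracies near 1.0 on
this cohort demonstrate that the training machinery works — not that the
features would separate real border-line arrhythmias, where measured
cohorts show substantially lower test accuracy.  Radar-route test
features additionally inherit the 20 Hz slow-axis timing noise
(sub-sample refinement reduces it to a few ms per beat).

## Problem sizes

Defaults were chosen so a full test run and the acceptance script each
complete in well under a minute on one core: observations are single
25.6 s windows (512 chirps × 100 fast-time samples), the training cohort
is 33 ECG records of ~10 s, the radar test cohort 15 subjects × 10
observations, SNR comparisons use 20 seeded trains, and the
Fourier-coefficient oracle integrates 10⁶ points per pulse over a
24-combination parameter grid.

## Known limitations

- Single target, single reflection: no clutter, multipath or
  multi-person separation; the angle term is simulated for one arrival.
- The energy threshold E_th = 0.04 rad² is calibrated to the cardiac
  band at 77 GHz; other carriers or displacement scales require rescaling.
- The causal filtering mode degrades HR accuracy below ~1 Hz heart rate
  (see the zero-phase rationale above).
- The ECG generator does not model beat-morphology pathology; beat-type
  classification (PVC vs APC) is out of scope.
- Reported classifier accuracies are for the synthetic cohort's idealized
  class separation.
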