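# Methods

`caepdetect` implements objective detection of cortical auditory evoked
potentials (CAEPs) — slow (≤15 Hz) EEG deflections within ~700 ms of a
sound — from ensembles of stimulus-locked epochs, together with the
simulation and evaluation machinery needed to characterize detector
specificity, sensitivity and reliability. This note documents the models,
the defaults and their rationale, the numerical choices, and the limits of
what the shipped synthetic data can show.

## Signal model and preprocessing

A recording is a single EEG channel sampled at `fs` (default 500 Hz) with
stimuli presented periodically (default 0.9 Hz), giving contiguous epochs of
`floor(fs / rate)` = 555 samples (~1111 ms). Detectors analyze the first
700 ms (350 samples) after onset. Preprocessing follows standard
evoked-potential practice: a 1–15 Hz 3rd-order Butterworth band-pass and
rejection of any epoch containing a sample beyond ±110 µV (inclusive bound).

The band-pass is applied **zero-phase** (forward–backward), which preserves
peak latencies at the cost of doubling the effective attenuation (the
magnitude response is squared). A causal single pass would shift latencies,
which matters when templates are compared across methods; zero-phase is the
common offline choice and is what the filter-response tests assume.

## Features

* **Voltage means** (time domain): the mean voltage over consecutive 50 ms
  intervals of the analysis window, giving Q = 14 features for the 700 ms
  window. Epoch rows are averaged into the mean feature vector x̄.
* **Fourier features** (frequency domain): real and imaginary parts of the
  unnormalized per-epoch DFT at selected bins ("spectral bands"); bin k of
  the 350-sample window sits at k·fs/T ≈ 1.43·k Hz. The transform is applied
  to individual epochs, never to the coherent average — phase alignment
  across epochs is exactly the signal being tested.
* **Polar features**: per-epoch amplitude r and phase a ∈ [−π, π] of those
  bins; zero-amplitude components get phase 0 by convention (affects only
  pathological inputs).

Default band sets (700 ms / 500 Hz window): the frequency-domain T² uses the
six bins at {5.7, 4.3, 7.1, 2.9, 1.4, 8.6} Hz (SNR-ranked); the q-sample
statistics use bins 1–7 (1.4–10 Hz); the diagonal T² uses all bins with
centers at or below 15 Hz (bins 1–10) with rule-of-thumb weights 1 below
8 Hz, 0.75 for 8–9 Hz, and 0.5 for 9–15 Hz. Band membership for the diagonal
statistic is implied by its weight rule rather than printed anywhere; the
1–15 Hz coverage matches the preprocessing band.

## Detection statistics

All tests share the null hypothesis "no response": the mean feature vector
is zero (high-pass filtering removes the mean; under stationary noise the
spectral phases are uniform so Fourier features are centered on zero).

* **T²_Time / T²_Freq** — the one-sample Hotelling statistic
  T² = N (x̄−µ) S⁻¹ (x̄−µ)ᵀ with the full sample covariance S (N−1
  denominator). Inference uses the exact transform
  F = (N−p)/(p(N−1))·T² ~ F(p, N−p), with p = Q or 2W.
* **T²_Toep** — the same quadratic form with S replaced by a Toeplitz
  matrix: for stationary noise the covariance of successive interval means
  depends only on lag, so S is determined by Q autocovariances γ(0..Q−1)
  estimated from the *continuous* recording's interval-mean sequence — far
  more data per parameter than the N×Q epoch matrix offers. The biased
  (1/M) mean-subtracted autocovariance is used because it guarantees a
  positive-semidefinite matrix. When no raw trace accompanies an ensemble,
  the concatenation of the full epochs in order stands in for it.
* **T²_Diag** — for stationary noise, distinct spectral bands (and the real
  and imaginary parts within a band) are asymptotically independent, so S
  reduces to the per-feature variances S_i: the statistic is
  Σ (w_i x̄_i − µ_i)² / S_i. The weights w touch only the mean vector;
  variances are computed from unweighted features.
* **QMod V1–V4** — amplitude-weighted q-sample uniform-scores statistics on
  spectral phases: Σ_j [(Σ_i r_ij cos θ_ij)² + (Σ_i r_ij sin θ_ij)²]. Each
  of amplitude r and phase θ enters either as its actual value or as its
  rank, ranked **jointly** across all epochs and bands (1..N·W, average
  ranks on ties); rank-mode phases are mapped to angles by rank·2π/(N·W).
  V3 (phase values, amplitude ranks) is the default variant.

Two deliberate readings are documented here because the source formulas are
ambiguous. First, the Toeplitz and diagonal statistics are implemented as
plain quadratic forms *without* the leading N of the classical T²; since
their null distributions come from applying the identical functional to
bootstrap surrogates of the same N, any fixed factor cancels. Second,
value-mode phases enter QMod as raw angles; the 2π/(N·W) factor applies
only to ranks (it is what converts a rank into a position on the circle —
scaling raw radians by it would collapse all phases toward zero and destroy
the test's power).

## Frequency-domain bootstrap

The modified statistics have no tractable null distribution, so inference
uses surrogate recordings that preserve the observed power spectrum and
serial correlation while destroying any phase-locked response:

1. Welch PSD of the continuous recording (2 s Hann windows, 50% overlap).
   The 2 s window is the binding smoothing parameter: enough smoothing to
   wash out stimulus-locked spectral peaks that would otherwise bias the
   null toward the alternative.
2. Per-bin power perturbation by independent unit-mean exponential draws —
   the fluctuation law of raw periodogram ordinates.
3. Uniform random phases and inverse FFT, producing a real surrogate series
   of the same length as the observed recording.
4. The surrogate is epoched with the observed geometry and the detector
   re-applied (for T²_Toep the covariance is re-estimated per surrogate),
   yielding B = 1000 null statistics. The p-value is
   (1 + #{null ≥ observed}) / (B + 1), strictly positive and valid for
   finite B.

Surrogacy is at the level of the continuous recording, not the epoch, so
serial correlation crossing epoch boundaries is preserved. Numerically,
steps 2–3 are sampled by drawing each interior bin as a circular complex
Gaussian with variance equal to the target power — *exactly* the same
distribution (a complex Gaussian has exponential power and uniform phase)
without the trig calls; only the two real bins (DC, Nyquist) differ in
fluctuation law, and both are essentially empty after the 1–15 Hz band-pass.
Surrogates are generated at the next fast FFT length and truncated to the
recording length; the process is stationary, so a truncated draw is still a
draw. Vectorized batch implementations of the bootstrap statistics (module
`_fast`) are asserted equal to the scalar definitions in the test suite.
All randomness flows from one seed through spawned substreams.

## Synthetic data

The simulator reproduces the study conditions the detectors are meant for:

* **Background EEG**: stationary Gaussian colored noise from order-20
  autoregressive models (Yule–Walker fits on the biased autocovariance),
  band-pass filtered 1–15 Hz. The shipped presets are AR(20) Yule–Walker
  solutions matching EEG-like low-frequency-dominant target spectra
  (corner frequencies 1.8–4.5 Hz, roll-off exponents 3–4.5, one preset with
  a mild alpha-range bump; raw sd 18–30 µV) plus a 10⁻³ relative broadband
  floor. The floor mirrors the instrument/far-source noise present in any
  measured EEG and keeps the Yule–Walker system well conditioned, so the
  AR coefficients remain identifiable from simulated data rather than only
  the spectrum. After filtering, every preset has >80% of its power below
  10 Hz. Each simulated ensemble draws its preset at random, emulating
  across-subject spectral variability.
* **Responses**: deterministic templates built as sums of Gaussian-windowed
  deflections (25–60 ms sd), spanning early/late, positive/negative and
  mono- to triphasic morphologies, including an adult-like P1–N1–P2. The
  widths are chosen so the library's band-SNR profile against the noise
  presets peaks in the 3–7 Hz range — the spectral signature of cortical
  responses that motivates the default band sets. Under the alternative a
  randomly chosen template is added identically to every epoch.
* **Effect size**: SNR = 10·log₁₀(p_signal/p_noise), with p_signal the mean
  power of the coherently averaged epoch and p_noise the mean square of the
  continuous recording. Templates are scaled by **expected** powers
  (template power over realized noise power, both over the full epoch), so
  the injected effect size does not inherit noise from the coherent
  average; the realized estimator then scatters slightly above the target
  (by ≈10·log₁₀(1 + p_noise/(N·p_signal))). Replication studies use
  N ∈ {20, 40, 80, 160} and SNRs from −20 to −8 dB.
* Template injection happens after noise filtering — templates are already
  band-limited by construction, and injecting first would distort their
  calibrated power. AR generation discards a burn-in of 10× the model
  order; recording length is derived from the epoch count and stimulus
  rate, never configured independently.

What the synthetic data does **not** emulate: nonstationary noise (drowsy /
alert state changes), trial-to-trial response variability (habituation),
artifacts beyond amplitude excursions, or multi-channel structure. Passing
calibration and power tests on this generator therefore demonstrates the
statistical machinery under the stated stationary-Gaussian assumptions, not
performance on clinical recordings.

## Evaluation machinery

False-positive and detection rates are empirical proportions; their
acceptance bands are exact Binomial(M, α) intervals whose endpoints are
**mid-distribution quantiles** (smallest k with P(X<k) + P(X=k)/2 ≥ tail
mass, divided by M) — the standard inversion of a discrete CDF, which for
M = 10,000 at α = 0.01 gives the 99% band [0.0076, 0.0127]. Per-method
α-adjustment takes the empirical (1−target) quantile of a null sample as
the decision threshold, reported as the midpoint between the bracketing
order statistics; on the p-value scale the same rule yields an adjusted
nominal α. Method comparisons use two-sided Fisher's exact tests
(point-probability rule; sidedness is a choice — the comparisons are
exploratory). Reliability uses Cohen's κ = (P_o − P_c)/(1 − P_c) with the
large-sample standard error SE = sqrt(P_o(1−P_o)/(n(1−P_c)²)); ambiguous
examiner outcomes are mapped to non-detections before tabulation.

## Problem sizes in the shipped studies

The test suite replicates the simulation study at sizes chosen as a
practical desk-scale design: 10,000 null ensembles per condition for the
F-inferred detectors (the full published size); 1,000 null ensembles ×
1,000 surrogates for the bootstrap-inferred detectors, with the acceptance
band widened accordingly to the exact M = 1,000 interval; 500 ensembles per
cell for sensitivity and power-monotonicity studies, where detection-rate
differences of interest are an order of magnitude larger than the ±0.045
Monte-Carlo noise. Power monotonicity uses decisions at the empirical 1%
null quantile of each statistic (threshold form of α-adjustment) rather
than per-ensemble bootstraps: the two decision rules agree by construction
on marginal calibration, and the threshold form keeps the study a pure
function of the statistic.

## Known limitations

* The Toeplitz statistic assumes the analyzed window shares the stationary
  covariance of the whole recording; a strong response violates this under
  H1 (harmless for detection, since only the H0 distribution is
  bootstrapped, but the statistic is not a likelihood ratio).
* Bootstrap p-values inherit Welch-PSD estimation variance; at small N the
  modified statistics run slightly liberal before α-adjustment.
* The F route requires N > p; with Q = 14 voltage means the time-domain
  test needs at least 15 artifact-free epochs.
* Rank-amplitude QMod variants do not vanish on identically-zero ensembles
  (tied ranks are positive); this degenerate input cannot occur with
  continuous noise.
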