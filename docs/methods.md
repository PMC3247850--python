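# Methods

## The decoding problem

During repetitive foot dorsiflexion, EEG power over the foot motor area
(electrode Cz, mid-central) drops across a broad 8–50 Hz band — an
event-related desynchronization (ERD). The pipeline turns this contrast into
a binary brain switch: an offline stage learns a subject-specific prediction
model from cued training trials; a calibration stage picks two posterior
thresholds; an online stage scores 0.5-s EEG segments in real time and
drives a two-state machine that switches a (virtual) FES actuator on and
off.

## Offline model

Each ~6-s trial is band-pass filtered (0.01–50 Hz, zero phase), re-referenced
to the common average of the retained channels, and reduced to integrated
periodogram power in 2-Hz bins centered at 1, 3, …, 49 Hz (25 bins × C
channels). The classifier-facing representation is **log** band power: raw
integrated power is approximately scaled chi-squared, so its variance grows
with its mean and any variance-based subspace method would lock onto the
large low-frequency bins; the log stabilizes the variance and is the
standard EEG band-power representation. The same transform is applied at
training and online time, so the linear maps below always act on log power.

**Artifact-channel rejection.** Per channel, the per-trial statistic is the
maximum absolute voltage. A trial is an outlier for a channel when the
statistic exceeds median + k·(1.4826·MAD) over trials (k = 6 nominally).
Channels that are outliers in more than 25% of trials are dropped first;
k then escalates (×1.1 per step) until the fraction of trials that are
outliers on any retained channel is at most 5%; the procedure repeats on the
reduced set until stable. Screening runs on the **raw, unfiltered,
unreferenced** amplitudes: the 0.01-Hz high-pass has a seconds-long kernel
that smears large artifacts into neighboring epochs as slow drifts, and a
common average over contaminated channels would smear them into every
channel. The retained set is then filtered and re-referenced to its own
common average (the standard re-referencing order after bad-channel
rejection).

**Feature extraction.** Classwise PCA: each class's trials get their own
principal basis retaining ≥ 95% of that class's variance (`variance_kept`,
data-driven subspace dimension). Within each class subspace a supervised
1-D direction is fit on all trials. The default is the Fisher discriminant
with Ledoit–Wolf shrinkage of the within-class covariance — with ~100 trials
in a subspace of comparable dimension the sample covariance is badly
conditioned, and the shrunk estimator interpolates between the whitened
Fisher direction and the plain class-mean difference as the data demand. An
approximate-information discriminant (gradient ascent on a Gaussian-entropy
mutual-information surrogate, Fisher-initialized) is available behind the
same interface (`method="aida"`); the two agree closely when class
covariances are similar.

**Classifier.** The two piece features (one per class subspace) are two
strongly correlated linear views of the same trial, so the class-conditional
model is a bivariate Gaussian per class — per-piece means and variances plus
the cross-covariance. Treating the pieces as independent (naive-Bayes
fusion) double-counts evidence and saturates the posteriors, which in turn
degenerates the calibration thresholds; conditioning on both features with
their correlation gives honestly calibrated posteriors. Priors default to
the empirical class frequencies. Variances carry a floor of 1e-9 × the
overall feature variance; the cross-correlation is clamped inside (−1, 1).
A posterior tie classifies as idle — the machine never stimulates on
ambiguity.

**Band search and validation.** Accuracy is estimated by 5 runs of
stratified 10-fold cross-validation, extractor and classifier refit inside
every training fold. The frequency range starts at the full band; the lower
edge F_L rises in 2-Hz steps while the CV accuracy strictly improves (a tie
stops the search — the smaller model wins), then the upper edge F_H descends
likewise. Fold assignments are fixed across candidate bands so candidates
are compared on identical splits. Exact binomial upper-tail probabilities
(computed in log space) quantify how likely a chance classifier is to reach
a given accuracy.

## Calibration and online operation

Online, consecutive non-overlapping 0.5-s segments are independently
re-referenced (over the model's channels), filtered, binned over the model's
band, and scored. Two segment-level corrections matter:

- **Segment-length statistics.** A 2-Hz bin of a 6-s trial averages 12
  periodogram ordinates; a 0.5-s segment has one. The log of a
  Gamma-distributed power estimate carries a known bias (ψ(n) − ln n) and
  variance (ψ₁(n)), both of which propagate through the linear feature maps
  in closed form, so the class means, variances and cross-covariance are
  corrected analytically for the online segment length rather than refit
  (`segment_adjusted_classifier`). The correction treats bin noise as
  independent across bins and channels — an approximation when channels are
  correlated.
- **Consistent-statistic calibration.** The state machine thresholds the
  **1.5-s moving average** P̄ of the posterior, so the calibration medians
  are taken over that same averaged statistic: T1 = median of P̄ during
  dorsiflexion, T2 = median during idling, from a 20-s-alternating
  calibration run (~3 min). Per-step posteriors are strongly skewed toward
  0/1, and the median of the raw posteriors sits above the typical averaged
  value, which would make the trigger systematically too strict.

The state machine updates every 0.5 s on the mean of the last k = 3
posteriors (startup averages what exists): idle → dorsiflexion when
P̄ > T1, dorsiflexion → idle when P̄ < T2, both strict (equality holds the
state); between the thresholds the state is held (hysteresis). Stimulation
commands carry on/off plus an amplitude in [0, 100] mA; inactive commands
carry zero amplitude, and stimulation is never active in the idle state.
The virtual actuator responds with a sustained ~17° dorsiflexion (first-order
rise, τ = 0.1 s, configurable latency): tetanic surface FES holds the foot
dorsiflexed rather than cycling it.

## Performance analysis

Goniometer traces are smoothed with a 100-ms Gaussian window (SD =
width/6, ≥ 99.7% of mass inside the window) and binarized by threshold
crossing (default 5°). The normalized cross-covariance

ρ(m) = Σᵢ (x[i−m] − x̄)(y[i] − ȳ) / √(Σᵢ(x[i] − x̄)² · Σᵢ(y[i] − ȳ)²)

uses full-series means and sums; out-of-range terms contribute zero; the lag
axis is oriented so a positive best lag m* = argmaxₘ ρ(m) means the response
follows the voluntary trace. For session analysis the search is restricted
to |m| ≤ 5 s (the full-series normalization shrinks extreme lags, but a
restricted window avoids spurious boundary maxima); ties resolve to the
smallest |m|. Both timelines are resampled to a common 256 Hz clock first.
An omission is a voluntary-dorsiflexion cue interval containing no response
initiation (0 → 1 transition); a false alarm is an initiation inside an
idling interval — only initiations matter, not durations.

**Monte Carlo chance null.** Per trial, the classifier's per-step label is
replaced by a fair coin flip (P(D) ∈ {0, 1} at 2 decisions/s), passed
through the same 1.5-s averaging and hysteresis machine (default
T1 = T2 = 0.5; session thresholds and an averaging bypass are exposed as
options, since the construction admits several readings), and the resulting
timeline is scored by ρ* against the voluntary timeline of the standard
session (10 alternating pairs of 10-s epochs). The null searches the full
lag domain, matching the definition of the best-lag correlation. Constant
response timelines receive ρ* = 0 by convention so a 10,000-trial run never
aborts. Because both timelines are piecewise constant on 0.5-s blocks, ρ(m)
is piecewise linear in the lag with knots on the 0.5-s grid, so the
computation runs exactly on the decision clock (~100× faster than
resampling; a test verifies the equality). At 10,000 trials the maximum ρ*
is ≈ 0.33–0.36 across seeds; the alternative constructions (bypassed
averaging, calibrated-strength hysteresis) bracket it at ≈ 0.21 and
≈ 0.46–0.54.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, not
the biophysics of EEG:

- **Background**: 12 colored-noise sources (white floor + 1/f trend + mu/beta
  spectral bumps) at random scalp locations, mixed with a tight spatial
  Gaussian (scale 0.03 m; adjacent-electrode correlation ≈ 0.3), plus
  equal-RMS per-channel noise; ~10 µV RMS per channel.
- **In-band rhythm**: inside the ERD band the signal is predominantly
  oscillatory — one tonal component per 2-Hz analysis bin, placed on the
  bin's exact Fourier frequency (leakage-free at both 6-s and 0.5-s window
  lengths), with slowly drifting scalp-coherent amplitudes (per-tone
  envelopes, log-SD 0.15) plus a band-limited noise floor (5% of in-band
  power). Oscillations with second-scale envelopes are what make 0.5-s
  band-power estimates nearly as reliable as trial-length ones, as in real
  EEG; with a pure-noise in-band model, tone×noise interference dominates
  short-segment feature noise and online decoding cannot match its offline
  accuracy.
- **Amplitude variability**: the whole in-band component is modulated by a
  global (scalp-coherent, arousal-like) log-normal process (SD 0.3) and a
  smaller per-channel process (SD 0.1), both with ~1-s correlation time.
  The 1-s timescale matters twice: mu/beta envelopes genuinely fluctuate on
  the order of a second, and longer correlation times make adjacent trials
  (which alternate in class) share drift, pushing null-subject
  cross-validation significantly below chance (temporal-leakage
  anti-learning).
- **ERD**: the in-band component of the ERD channels is multiplied by
  √(1 − depth) during dorsiflexion epochs (no ramp), so band power drops by
  exactly (1 − depth) in expectation; the effect leaks to neighboring
  electrodes with exponential distance decay (scale 0.025 m, cut off at
  0.06 m) so topographies are non-degenerate, while distant channels carry
  no class information. Default depth 0.7 (a deep broadband
  desynchronization). Subject traits (spectral profiles, tone weights and
  phases, source geometry) are drawn from a separate `subject_seed`, so
  training, calibration and online sessions can realize the *same subject*
  under independent noise — without this, calibration does not transfer and
  closed-loop behavior collapses.
- **Artifacts**: designated "hat band" channels (Fp1/Fp2, T7/T8, O1/O2)
  carry 10× amplitude in a random 40% of epochs, emulating EMG
  contamination.
- **Goniometer**: during dorsiflexion epochs the voluntary ankle performs a
  whole number of (1 − cos) cycles at 1.25 Hz, 17° peak, returning to rest
  at each cue boundary, over 0.3° baseline noise; the second (stimulated)
  ankle is noise-only in training recordings.

The reference parameterization was calibrated against the study-level
observables such a system reports — per-subject offline accuracy in the
high-80s-to-high-90s percent range, selected bands with F_L around 2–10 Hz
and F_H near 50 Hz, flawless online response (every movement epoch answered,
at most an occasional false alarm), lags of ~1–3 s and session correlations
ρ* ≈ 0.45–0.65. At the defaults the synthetic reference subject sits at the
clean end of that envelope (offline CV ≈ 0.99–1.0); `erd_depth ≈ 0.5–0.6`
produces weaker subjects (CV ≈ 0.85–0.97) whose online runs occasionally
drop an epoch or emit a false alarm.

**What passing tests do not show.** The generator's rhythm is tonal on the
analysis grid, its ERD switches instantaneously at cue boundaries, its
artifacts are pure gain changes, and its spatial mixing is a smooth
Gaussian — real EEG has none of these conveniences. Pipeline performance on
this generator demonstrates correctness of the machinery (recovery of an
injected contrast, honest nulls, causal online behavior), not expected
performance on human data.

## Numerical choices

- **Filtering**: zero-phase spectral filter with a Butterworth-type
  magnitude response (order 16 in power) per edge. A forward–backward IIR
  design is numerically unusable at a 0.01-Hz edge with fs = 256 (poles
  ~1e-4 inside the unit circle; 35% passband error on 6-s records), while
  the spectral filter meets the passband (±5%) and stopband (≥ 20 dB one
  octave out) contracts identically on long records and 0.5-s segments.
- **Binning**: bins are half-open intervals (c−1, c+1] around odd centers,
  disjoint and complete over (0, 50]; DC is excluded; PSD density is
  integrated (× Δf), making the feature scale duration-invariant in
  expectation.
- **Epoch timing**: half-open [start, start + epoch_len), sample index
  ⌊t·fs⌋, 0-based.
- **Robust scale**: 1.4826 × MAD (Gaussian-consistent).
- **Degenerate inputs**: constant timelines are rejected in session analysis
  but scored ρ* = 0 in the Monte Carlo null; a calibration with T1 ≤ T2 is
  reported as a warning and the machine still runs; all-channel rejection,
  zero-variance classes, absent calibration states, and posterior inputs
  outside [0, 1] raise errors.
- **Determinism**: every stochastic component is driven by explicit integer
  seeds; identical configuration yields bit-identical recordings, fold
  tables, and decision trajectories.

## Limitations

- The AIDA-style discriminant is a surrogate objective (Gaussian-entropy
  mutual information), not a reimplementation of any specific published
  optimizer; the Fisher default is used throughout the tests.
- The segment-length correction assumes independent bin noise; with strongly
  correlated channels it overestimates the variance inflation, which is
  conservative (posteriors too soft, never too sharp).
- The Monte Carlo null construction is under-determined in several details
  (threshold regime, averaging); the shipped default (hard labels, averaging,
  T1 = T2 = 0.5) is one documented reading, and the alternatives are
  exposed as options rather than resolved silently.
- Multiclass decoding, nonlinear decoders, ICA-based artifact correction,
  bad-trial rejection, and real stimulation hardware are out of scope.
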