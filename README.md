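# bcifes

An EEG brain-computer-interface pipeline for detecting repetitive foot
dorsiflexion versus idling and driving a (virtual) functional-electrical-
stimulation (FES) actuator — the kind of system studied for restoring foot
movement after stroke or spinal cord injury (foot drop).

The package implements the complete decoding chain, exercised end to end on
synthetic EEG so every stage is testable without any human recordings:

1. **Synthetic acquisition** (`bcifes.synth`) — 64-channel, 256 Hz surrogate
   EEG with a broadband (8–50 Hz) event-related desynchronization (ERD) at
   electrode Cz during dorsiflexion epochs, artifact-contaminated "hat band"
   channels, and ankle goniometer traces (1.0–1.5 Hz dorsiflexion cycles).
2. **Preprocessing** (`bcifes.preprocess`) — zero-phase 0.01–50 Hz band-pass,
   trial segmentation from cues or the goniometer, iterative artifact-channel
   rejection with robust (median/MAD) statistics, common average reference
   over the retained channels.
3. **Spectral features** (`bcifes.spectral`) — FFT periodogram power
   integrated in 2-Hz bins centered at 1, 3, …, 49 Hz (25 bins per channel),
   plus the class-contrast SNR spectrum
   SNR(f) = (μ_i − μ_d)² / (σ_i² + σ_d²).
4. **Decoding** (`bcifes.decode`) — classwise principal component analysis
   (one subspace per class, the piecewise-linear map Φ_C) with a supervised
   1-D discriminant per subspace (f = T_A Φ_C(d)), and a Gaussian Bayesian
   classifier on the piece features, P(I|f*) vs P(D|f*).
5. **Model selection** (`bcifes.selection`) — 5×10 stratified cross-validation,
   greedy 2-Hz frequency-band search for [F_L, F_H], exact binomial
   chance-level significance, and hysteresis-threshold calibration
   (T1 = median P̄(D|dorsiflexion), T2 = median P̄(D|idle)).
6. **Online decoding** (`bcifes.online`) — non-overlapping 0.5-s EEG segments
   scored in (simulated) real time; posteriors averaged over 1.5 s drive a
   binary state machine: idle → dorsiflexion when P̄ > T1 (stimulation on),
   dorsiflexion → idle when P̄ < T2 (stimulation off).
7. **Evaluation** (`bcifes.evaluate`) — goniometer smoothing/binarization,
   normalized cross-covariance ρ(m) with best lag m*, omission and
   false-alarm counts, and a 10,000-trial Monte Carlo chance null for ρ*.

## Worked example

Train, calibrate and run one synthetic subject through the closed loop
(reduced size so it finishes in under a minute):

```python
from bcifes.synth import SynthConfig
from bcifes.workflow import end_to_end

cfg = SynthConfig(n_channels=16, n_epochs_per_class=30, fs_gonio=500.0)
result = end_to_end(seed=1, train_cfg=cfg, folds=5, runs=2)
model, thr, report = result["model"], result["thresholds"], result["report"]
print(f"CV accuracy : {model.cv_accuracy:.3f}")
print(f"band        : {model.band[0]:.0f}-{model.band[1]:.0f} Hz")
print(f"T1, T2      : {thr.T1:.3f}, {thr.T2:.3f}")
print(f"lag         : {report.lag_s:.2f} s")
print(f"rho*        : {report.rho_star:.2f}")
print(f"omissions   : {report.omissions}, false alarms: {report.false_alarms}")
```

prints

```
CV accuracy : 1.000
band        : 0-50 Hz
T1, T2      : 0.947, 0.046
lag         : 1.71 s
rho*        : 0.54
omissions   : 0, false alarms: 0
```

The cross-validated accuracy is the offline separability of idling vs
dorsiflexion trials; T1/T2 are the calibrated hysteresis thresholds on the
averaged posterior; the lag is how far the virtual FES response trails the
voluntary movement; ρ* is the best-lag temporal correlation between the two
movement timelines; omissions/false alarms count movement epochs with no
stimulation response and stimulation initiated during idling.

The same chain is available as a CLI:

```sh
bcifes simulate --out rec.h5 --seed 1
bcifes preprocess --in rec.h5 --out epochs.h5
bcifes train --in epochs.h5 --out model.h5 --folds 10 --runs 5 --seed 1
bcifes calibrate --model model.h5 --in calib.h5 --out thresholds.json
bcifes run-online --model model.h5 --thresholds thresholds.json --in sess.h5 --out run.h5
bcifes evaluate --run run.h5 --in sess.h5 --out report.json
bcifes mc-null --n 10000 --seed 1 --out null.json
bcifes end2end --out results/ --seed 1        # all of the above, chained
```

## Scope

Physical stimulation hardware (stimulator, microcontroller, electrode
electronics) is out of scope; the stimulator is modeled as an on/off +
amplitude command contract with a virtual mechanical response. See
`docs/methods.md` for the model details, the synthetic-data assumptions, and
known limitations.
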