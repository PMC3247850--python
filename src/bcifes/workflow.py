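"""End-to-end orchestration: training, calibration, online run, evaluation.

These helpers chain the pipeline stages with their standard settings:
common-average reference and 0.01-50 Hz band-pass on the continuous record,
goniometer-based trial segmentation, artifact-channel rejection, greedy
frequency-band search with repeated stratified cross-validation, posterior
threshold calibration on a separate alternating session, and the closed-loop
online run against a virtual stimulator.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .evaluate import PerformanceReport, evaluate_run
from .online import ACQUISITION_BAND, OnlineRunResult, posterior_stream, run_online_session
from .preprocess import (
    ArtifactParams,
    EpochSet,
    bandpass,
    common_average_reference,
    reject_artifact_channels,
    segment_epochs,
)
from .selection import PredictionModel, Thresholds, estimate_thresholds, search_frequency_band
from .synth import Recording, SynthConfig, generate_recording

__all__ = [
    "preprocess_recording",
    "train_from_recording",
    "calibrate_from_recording",
    "run_and_evaluate",
    "end_to_end",
]

logger = logging.getLogger(__name__)


def preprocess_recording(
    rec: Recording,
    epoch_len: float | None = None,
    source: str = "goniometer",
    artifact_params: ArtifactParams | None = None,
    gonio_threshold: float = 5.0,
) -> EpochSet:
    """Segment, artifact-screen, filter, and re-reference one training recording.

    Artifact channels are identified on the raw, unreferenced amplitudes: the
    0.01 Hz high-pass has a seconds-long kernel that smears large artifacts
    into neighboring epochs as slow drifts, and a common average computed over
    contaminated channels would smear them into every channel — screening must
    precede both.  The retained channels are then band-pass filtered and
    re-referenced to their own common average (the standard re-referencing
    order after bad-channel rejection).
    """
    rec.validate()
    if epoch_len is None:
        epoch_len = min(end - start for start, end, _ in rec.cue_schedule)
    raw_epochs = segment_epochs(rec, epoch_len, source=source, gonio_threshold=gonio_threshold)
    mask = reject_artifact_channels(raw_epochs, artifact_params)

    filtered = bandpass(rec.eeg, rec.fs_eeg, *ACQUISITION_BAND)
    epochs = segment_epochs(
        replace_rec(rec, eeg=filtered), epoch_len, source=source, gonio_threshold=gonio_threshold
    )
    epochs.retained_mask = mask
    for t in range(epochs.n_trials):
        epochs.data[t, mask, :] = common_average_reference(epochs.data[t, mask, :])
    return epochs


def replace_rec(rec: Recording, **kwargs) -> Recording:
    fields = dict(
        eeg=rec.eeg,
        fs_eeg=rec.fs_eeg,
        channel_labels=rec.channel_labels,
        goniometer=rec.goniometer,
        fs_gonio=rec.fs_gonio,
        cue_schedule=rec.cue_schedule,
    )
    fields.update(kwargs)
    return Recording(**fields)


def train_from_recording(
    rec: Recording,
    folds: int = 10,
    runs: int = 5,
    seed: int = 0,
    variance_kept: float = 0.95,
    method: str = "lda",
    source: str = "goniometer",
    artifact_params: ArtifactParams | None = None,
) -> PredictionModel:
    """Full offline stage: preprocessing + band search + final refit."""
    epochs = preprocess_recording(rec, source=source, artifact_params=artifact_params)
    model = search_frequency_band(
        epochs, folds=folds, runs=runs, seed=seed, variance_kept=variance_kept, method=method
    )
    logger.info(
        "trained model: band %s, %d channels, CV accuracy %.3f",
        model.band, len(model.channel_labels), model.cv_accuracy,
    )
    return model


def _true_state_per_step(rec: Recording, times: np.ndarray, step: float = 0.5) -> np.ndarray:
    """Cue class at each decoder step (judged at the segment midpoint)."""
    mid = times + step / 2.0
    state = np.full(times.shape, "I", dtype="<U1")
    for start, end, lab in rec.cue_schedule:
        state[(mid >= start) & (mid < end)] = lab
    return state


def calibrate_from_recording(
    model: PredictionModel, rec: Recording, averaging_window: float = 1.5, step: float = 0.5
) -> Thresholds:
    """Posterior-threshold calibration on an alternating idle/dorsiflexion run.

    The state machine compares the 1.5-s moving average of P(D) to the
    thresholds, so the calibration medians are taken over that same averaged
    statistic: per-step posteriors are strongly skewed toward 0/1, and the
    median of the raw posteriors sits above the typical averaged value,
    which would make the trigger systematically too strict.
    """
    times, p_d = posterior_stream(model, rec, step=step)
    k = max(1, int(round(averaging_window / step)))
    csum = np.cumsum(p_d)
    p_bar = np.empty_like(p_d)
    for j in range(len(p_d)):
        lo = max(0, j - k + 1)
        p_bar[j] = (csum[j] - (csum[lo - 1] if lo > 0 else 0.0)) / (j - lo + 1)
    states = _true_state_per_step(rec, times)
    return estimate_thresholds(p_bar, states)


def run_and_evaluate(
    model: PredictionModel,
    thr: Thresholds,
    rec: Recording,
    fes_amplitude: float = 90.0,
    threshold_deg: float = 5.0,
) -> tuple[OnlineRunResult, PerformanceReport]:
    """Closed-loop run over a session recording plus its performance report."""
    run = run_online_session(model, thr, rec, fes_amplitude=fes_amplitude)
    report = evaluate_run(
        voluntary_trace=rec.goniometer[0],
        fs_voluntary=rec.fs_gonio,
        response_trace=run.response_gonio,
        fs_response=run.response_fs,
        cue_schedule=rec.cue_schedule,
        threshold_deg=threshold_deg,
    )
    return run, report


def end_to_end(
    seed: int = 0,
    train_cfg: SynthConfig | None = None,
    folds: int = 10,
    runs: int = 5,
) -> dict:
    """Simulate, train, calibrate, run online and evaluate one synthetic subject.

    The training session uses the standard design (6-s epochs, 100 per class),
    calibration a 20-s alternating run, and the online session 10 alternating
    pairs of 10-s epochs.  Returns the model, thresholds, run and report.
    """
    # one subject (stable traits), three sessions (independent noise)
    base = train_cfg if train_cfg is not None else SynthConfig()
    base = replace(base, subject_seed=seed)
    train_rec = generate_recording(replace(base, seed=seed))
    model = train_from_recording(train_rec, folds=folds, runs=runs, seed=seed)

    calib_cfg = replace(base, epoch_len=20.0, n_epochs_per_class=5, seed=seed + 1)
    thr = calibrate_from_recording(model, generate_recording(calib_cfg))

    online_cfg = replace(base, epoch_len=10.0, n_epochs_per_class=10, seed=seed + 2)
    online_rec = generate_recording(online_cfg)
    run, report = run_and_evaluate(model, thr, online_rec)
    return {
        "model": model,
        "thresholds": thr,
        "run": run,
        "report": report,
        "online_recording": online_rec,
    }
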