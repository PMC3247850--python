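"""Real-time-style decoding loop and the binary stimulation state machine.

EEG is consumed in consecutive non-overlapping 0.5-s segments.  Each segment
is re-referenced, band-pass filtered, restricted to the model's channels,
spectrally binned over the model's band, mapped to per-piece features and
scored to a posterior P(D).  The posteriors are averaged over a 1.5-s moving
window and drive a two-state hysteresis machine: idle -> dorsiflexion when the
average exceeds T1 (stimulation on), dorsiflexion -> idle when it falls below
T2 (stimulation off); both comparisons are strict, so equality holds state.
A virtual stimulator responds with a sustained dorsiflexion on its goniometer
whenever, and only when, stimulation is active.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .decode import extract_feature, posterior
from .exceptions import DataError
from .preprocess import bandpass, common_average_reference
from .selection import PredictionModel, Thresholds
from .spectral import binned_psd, log_power
from .synth import DORSIFLEX, IDLE, Recording

__all__ = [
    "DecoderState",
    "StimCommand",
    "decoder_step",
    "posterior_stream",
    "run_online_session",
    "OnlineRunResult",
]

logger = logging.getLogger(__name__)

STEP_S = 0.5
ACQUISITION_BAND = (0.01, 50.0)


@dataclass(frozen=True)
class DecoderState:
    """State of the online decoder between steps."""

    state: str = IDLE  # "I" or "D"
    posterior_buffer: tuple[float, ...] = ()  # most recent P(D) values, newest last
    step_index: int = 0
    buffer_len: int = 3  # averaging_window / step

    def averaged_posterior(self) -> float:
        """Mean of the buffered posteriors (partial buffer during startup)."""
        if not self.posterior_buffer:
            return 0.0
        return float(np.mean(self.posterior_buffer))


@dataclass(frozen=True)
class StimCommand:
    """Command contract toward the (virtual) stimulator."""

    active: bool
    amplitude: float  # mA in [0, 100]
    timestamp: float  # s

    def __post_init__(self):
        if not (0.0 <= self.amplitude <= 100.0):
            raise DataError("stimulation amplitude must lie in [0, 100] mA")
        if not self.active and self.amplitude != 0.0:
            raise DataError("inactive command must carry zero amplitude")


def decoder_step(
    st: DecoderState,
    p_d: float,
    thr: Thresholds,
    amplitude: float = 90.0,
    timestamp: float | None = None,
) -> tuple[DecoderState, StimCommand]:
    """One 0.5-s transition of the binary state machine.

    Pushes ``p_d`` into the averaging buffer, compares the buffer mean to the
    hysteresis pair and emits the stimulation command for the new state.
    Strictly greater than T1 triggers, strictly less than T2 releases; a mean
    inside [T2, T1] leaves the state unchanged.
    """
    if not (0.0 <= p_d <= 1.0):
        raise DataError("posterior probability must lie in [0, 1]")
    buf = (st.posterior_buffer + (float(p_d),))[-st.buffer_len :]
    p_bar = float(np.mean(buf))
    state = st.state
    if state == IDLE and p_bar > thr.T1:
        state = DORSIFLEX
        logger.info("step %d: idle -> dorsiflexion (mean posterior %.3f > T1=%.3f)", st.step_index, p_bar, thr.T1)
    elif state == DORSIFLEX and p_bar < thr.T2:
        state = IDLE
        logger.info("step %d: dorsiflexion -> idle (mean posterior %.3f < T2=%.3f)", st.step_index, p_bar, thr.T2)
    new_st = DecoderState(
        state=state,
        posterior_buffer=buf,
        step_index=st.step_index + 1,
        buffer_len=st.buffer_len,
    )
    active = state == DORSIFLEX
    t = timestamp if timestamp is not None else (st.step_index + 1) * STEP_S
    cmd = StimCommand(active=active, amplitude=amplitude if active else 0.0, timestamp=t)
    return new_st, cmd


def _ordinate_counts(n_samples: int, fs: float, band) -> np.ndarray:
    """Number of periodogram ordinates falling in each 2-Hz bin."""
    from .spectral import bin_centers_in_band

    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    centers = bin_centers_in_band(band)
    return np.array(
        [max(int(((freqs > c - 1.0) & (freqs <= c + 1.0)).sum()), 1) for c in centers]
    )


def segment_adjusted_classifier(model: PredictionModel, seg_len_s: float):
    """Class models re-anchored to the log-periodogram statistics of short segments.

    The classifier's Gaussians are fit on log binned power of long training
    trials, where each bin averages many periodogram ordinates; an online
    segment averages far fewer (one ordinate per 2-Hz bin at 0.5 s), so the
    log features carry a known extra bias, E[ln(Gamma(n)/n)] = psi(n) - ln n,
    and extra variance psi_1(n).  Both propagate through the linear feature
    map analytically (bin noise treated as independent across bins and
    channels), so the class means and variances are corrected in closed form
    rather than refit.
    """
    from scipy.special import digamma, polygamma

    from .decode import CLASSES, GaussianPieceModel

    n_seg = int(round(seg_len_s * model.fs))
    n_train = int(round(model.train_seg_len_s * model.fs))
    c_on = _ordinate_counts(n_seg, model.fs, model.band)
    c_off = _ordinate_counts(n_train, model.fs, model.band)
    n_chan = len(model.channel_labels)
    # feature layout is (bins, channels) raveled, bins slowest
    k_on = np.repeat(c_on, n_chan).astype(float)
    k_off = np.repeat(c_off, n_chan).astype(float)
    bias = (digamma(k_on) - np.log(k_on)) - (digamma(k_off) - np.log(k_off))
    extra_var = polygamma(1, k_on) - polygamma(1, k_off)

    a_maps = {p: model.extractor.composed_map(p)[0] for p in CLASSES}
    means, variances = {}, {}
    for piece in CLASSES:
        a = a_maps[piece]
        shift = float(a @ bias)
        infl = float((a**2) @ np.maximum(extra_var, 0.0))
        means[piece] = {c: model.classifier.means[piece][c] + shift for c in CLASSES}
        variances[piece] = {
            c: model.classifier.variances[piece][c] + infl for c in CLASSES
        }
    # the bin noise is common to both piece projections, so it also inflates
    # the cross-covariance between the piece features
    cross_infl = float((a_maps[CLASSES[0]] * a_maps[CLASSES[1]]) @ np.maximum(extra_var, 0.0))
    covariances = {
        c: model.classifier.covariances.get(c, 0.0) + cross_infl for c in CLASSES
    }
    return GaussianPieceModel(
        means=means,
        variances=variances,
        covariances=covariances,
        priors=dict(model.classifier.priors),
    )


def posterior_stream(
    model: PredictionModel, rec: Recording, step: float = STEP_S
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step posterior P(D) over a recording, processed segment by segment.

    Each non-overlapping ``step``-second segment is reduced to the model's
    retained channels, re-referenced to their common average (artifact-prone
    channels stay out of the reference, mirroring the offline preprocessing),
    band-pass filtered to the acquisition band, binned over the model's
    frequency band and scored with the segment-length-adjusted classifier.
    Returns (segment start times, P(D) values).  A trailing partial segment
    is dropped with a log line.
    """
    rec.validate()
    have = {c: i for i, c in enumerate(rec.channel_labels)}
    missing = [c for c in model.channel_labels if c not in have]
    if missing:
        raise DataError(f"recording lacks model channels: {missing}")
    idx = np.asarray([have[c] for c in model.channel_labels])

    n_seg = int(round(step * rec.fs_eeg))
    n_steps = rec.eeg.shape[1] // n_seg
    dropped = rec.eeg.shape[1] - n_steps * n_seg
    if dropped:
        logger.info("dropping %d trailing samples (incomplete segment)", dropped)

    scorer = segment_adjusted_classifier(model, step)
    times = np.arange(n_steps) * step
    p_d = np.empty(n_steps)
    for k in range(n_steps):
        # the model's channels only: artifact-prone channels are excluded
        # before re-referencing, mirroring the offline preprocessing
        seg = rec.eeg[idx, k * n_seg : (k + 1) * n_seg]
        seg = common_average_reference(seg)
        seg = bandpass(seg, rec.fs_eeg, *ACQUISITION_BAND)
        vec = log_power(binned_psd(seg, rec.fs_eeg, model.band).ravel())
        f = extract_feature(model.extractor, vec)
        _, pd_k = posterior(scorer, f)
        p_d[k] = pd_k
    return times, p_d


@dataclass
class OnlineRunResult:
    """Trajectory of one closed-loop session."""

    times: np.ndarray  # segment start times (s)
    p_d: np.ndarray  # raw per-step posterior P(D)
    p_bar: np.ndarray  # averaged posterior used by the state machine
    states: np.ndarray  # decoder state after each step ("I"/"D")
    commands: list[StimCommand]
    response_gonio: np.ndarray  # virtual stimulated-ankle angle (degrees)
    response_fs: float


def run_online_session(
    model: PredictionModel,
    thr: Thresholds,
    rec: Recording,
    fes_amplitude: float = 90.0,
    averaging_window: float = 1.5,
    step: float = STEP_S,
    stim_latency: float = 0.0,
    response_fs: float = 256.0,
    response_amp_deg: float = 17.0,
) -> OnlineRunResult:
    """Run the full closed loop over a recording; deterministic given inputs.

    The virtual FES foot's goniometer shows a sustained ~15-20 degree
    dorsiflexion whenever, and only when, stimulation is active, after a fixed
    configurable latency.
    """
    times, p_d = posterior_stream(model, rec, step=step)
    k = max(1, int(round(averaging_window / step)))
    st = DecoderState(buffer_len=k)
    states, p_bar, commands = [], [], []
    for t, p in zip(times, p_d):
        st, cmd = decoder_step(st, float(p), thr, amplitude=fes_amplitude, timestamp=t + step)
        states.append(st.state)
        p_bar.append(st.averaged_posterior())
        commands.append(cmd)

    # synthesize the stimulated ankle's goniometer trace: tetanic stimulation
    # holds the foot dorsiflexed, so the response is a sustained plateau with
    # a first-order mechanical rise/relaxation (tau ~ 0.1 s)
    duration = len(times) * step
    n_resp = int(round(duration * response_fs))
    t_resp = np.arange(n_resp) / response_fs
    active_steps = np.asarray([c.active for c in commands])
    step_of_t = np.minimum((t_resp / step).astype(int), len(times) - 1)
    active_t = active_steps[step_of_t]
    if stim_latency > 0:
        shift = int(round(stim_latency * response_fs))
        active_t = np.concatenate([np.zeros(shift, dtype=bool), active_t])[:n_resp]
    tau = 0.1  # s, mechanical time constant of the stimulated ankle
    alpha = 1.0 - math.exp(-1.0 / (tau * response_fs))
    angle = np.zeros(n_resp)
    level = 0.0
    for i in range(n_resp):
        target = response_amp_deg if active_t[i] else 0.0
        level += alpha * (target - level)
        angle[i] = level

    return OnlineRunResult(
        times=times,
        p_d=p_d,
        p_bar=np.asarray(p_bar),
        states=np.asarray(states),
        commands=commands,
        response_gonio=angle,
        response_fs=response_fs,
    )
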