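"""Synthetic EEG / goniometer recordings with movement-related desynchronization.

Generates multichannel surrogate EEG whose statistical structure matches what the
decoding pipeline assumes: a colored-noise background (1/f trend + white floor +
narrowband mu/beta oscillators) on every channel, and a broadband power decrease
(event-related desynchronization, ERD) over the foot motor area (electrode Cz)
during epochs of repetitive foot dorsiflexion.  A paired goniometer trace records
the ankle angle of the "voluntary" foot (sinusoid-like dorsiflexion cycles at
1.0-1.5 Hz, ~15-20 degree peak) and of the contralateral, stimulated foot.

Inside the ERD band the signal is predominantly rhythmic (a tone bank on the
analysis bins with slowly drifting amplitudes, plus a band-limited noise
floor); the ERD scales this whole in-band component by ``sqrt(1 - depth)``
during dorsiflexion epochs, so the band power drops by a factor of exactly
``1 - depth`` in expectation.  The ERD source leaks to neighboring electrodes
with a distance-decaying depth so that topographic maps are non-degenerate;
channels outside the local neighborhood carry no class information.  Subject
traits (spectral profiles, tone weights and phases, source geometry) are
drawn from ``subject_seed``, so independent sessions can realize the same
subject.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, DataError

__all__ = [
    "SynthConfig",
    "Recording",
    "generate_recording",
    "generate_decision_stream",
    "montage_labels",
    "montage_positions",
]

IDLE = "I"
DORSIFLEX = "D"

#: distance (m) beyond which the ERD source does not leak at all
_LEAK_CUTOFF_M = 0.06


@functools.lru_cache(maxsize=1)
def _montage():
    # mne import is deferred: it is slow and only needed for labels/positions
    from mne.channels import make_standard_montage

    mon = make_standard_montage("biosemi64")
    pos = mon.get_positions()["ch_pos"]
    return list(mon.ch_names), {k: np.asarray(v, dtype=float) for k, v in pos.items()}


def montage_labels() -> list[str]:
    """The 64 scalp channel labels of the standard montage, in cap order."""
    return list(_montage()[0])


def montage_positions() -> dict[str, np.ndarray]:
    """3-D electrode positions (meters) keyed by channel label."""
    return dict(_montage()[1])


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic recording generator.

    Defaults mirror the acquisition and task design the pipeline targets:
    64 channels at 256 Hz, 6-s epochs, 100 epochs per class, a broadband
    (8-50 Hz) power decrease at Cz during dorsiflexion, artifact-contaminated
    circumferential ("hat band") channels, and 1.0-1.5 Hz dorsiflexion cycles
    recorded by a 4 kHz goniometer.
    """

    n_channels: int = 64
    fs_eeg: float = 256.0
    fs_gonio: float = 4000.0
    epoch_len: float = 6.0
    n_epochs_per_class: int = 100
    erd_channels: tuple[str, ...] = ("Cz",)
    erd_band: tuple[float, float] = (8.0, 50.0)
    erd_depth: float = 0.7
    artifact_channels: tuple[str, ...] = ("Fp1", "Fp2", "T7", "T8", "O1", "O2")
    artifact_gain: float = 10.0
    artifact_epoch_frac: float = 0.4
    dorsiflexion_rate: float = 1.25
    dorsiflexion_amp_deg: float = 17.0
    leak_scale_m: float = 0.025
    n_bg_sources: int = 12
    bg_spatial_scale_m: float = 0.03
    idio_frac: float = 1.0
    rhythm_amp_jitter: float = 0.3
    rhythm_amp_jitter_local: float = 0.1
    rhythm_amp_tau_s: float = 1.0
    osc_frac: float = 0.95
    seed: int = 0
    subject_seed: int | None = None  # stable subject traits; defaults to seed

    def validate(self) -> None:
        if not (0.0 <= self.erd_depth < 1.0):
            raise ConfigError(f"erd_depth must lie in [0, 1), got {self.erd_depth}")
        lo, hi = self.erd_band
        if not (0.0 < lo < hi < self.fs_eeg / 2):
            raise ConfigError(f"erd_band {self.erd_band} not inside (0, fs/2)")
        if self.epoch_len <= 0:
            raise ConfigError("epoch_len must be positive")
        if self.artifact_gain < 1.0:
            raise ConfigError("artifact_gain must be >= 1")
        if not (0.0 <= self.artifact_epoch_frac <= 1.0):
            raise ConfigError("artifact_epoch_frac must lie in [0, 1]")
        if self.n_epochs_per_class < 1:
            raise ConfigError("n_epochs_per_class must be >= 1")
        if not (2 <= self.n_channels <= 64):
            raise ConfigError("n_channels must lie in [2, 64]")
        if self.dorsiflexion_rate <= 0:
            raise ConfigError("dorsiflexion_rate must be positive")
        labels = set(self.channel_labels())
        for ch in tuple(self.erd_channels) + tuple(self.artifact_channels):
            if ch not in labels:
                raise ConfigError(f"unknown channel label {ch!r}")

    def channel_labels(self) -> list[str]:
        """Deterministic channel set: required labels plus cap-order fill."""
        full = montage_labels()
        if self.n_channels == len(full):
            return full
        required = [c for c in full if c in set(self.erd_channels) | set(self.artifact_channels)]
        if len(required) > self.n_channels:
            raise ConfigError("n_channels too small for erd/artifact channel set")
        chosen = set(required)
        for c in full:
            if len(chosen) >= self.n_channels:
                break
            chosen.add(c)
        return [c for c in full if c in chosen]


@dataclass
class Recording:
    """A raw acquisition unit: multichannel EEG + goniometers + cue schedule."""

    eeg: np.ndarray  # (channels, samples), microvolts
    fs_eeg: float
    channel_labels: list[str]
    goniometer: np.ndarray  # (2, samples), degrees; row 0 = voluntary ankle
    fs_gonio: float
    cue_schedule: list[tuple[float, float, str]]  # (start s, end s, "I"/"D")

    def validate(self) -> None:
        if self.eeg.ndim != 2 or self.eeg.shape[0] != len(self.channel_labels):
            raise DataError("eeg shape inconsistent with channel_labels")
        if not np.isfinite(self.eeg).all():
            raise DataError("eeg contains non-finite values")
        prev_end = -math.inf
        for start, end, lab in self.cue_schedule:
            if lab not in (IDLE, DORSIFLEX):
                raise DataError(f"cue label {lab!r} not in {{I, D}}")
            if start < prev_end or end <= start:
                raise DataError("cue intervals must be time-ordered and non-overlapping")
            prev_end = end
        t_eeg = self.eeg.shape[1] / self.fs_eeg
        t_gon = self.goniometer.shape[1] / self.fs_gonio
        if abs(t_eeg - t_gon) > 1.0 / min(self.fs_eeg, self.fs_gonio) + 1e-9:
            raise DataError("goniometer and eeg span different time ranges")

    @property
    def duration(self) -> float:
        return self.eeg.shape[1] / self.fs_eeg


def _background_psd_profile(f: np.ndarray, mu_amp: float, beta_amp: float) -> np.ndarray:
    """Power profile: white floor + 1/f trend + mu (10 Hz) and beta (20 Hz) bumps."""
    white = 1.0
    pink = 8.0 / (f + 0.5)
    osc = mu_amp * np.exp(-0.5 * ((f - 10.0) / 0.8) ** 2)
    osc += beta_amp * np.exp(-0.5 * ((f - 20.0) / 1.0) ** 2)
    return white + pink + osc


def _draw_profile_params(rng: np.random.Generator) -> tuple[float, float]:
    return float(rng.uniform(3.0, 6.0)), float(rng.uniform(1.5, 3.0))


def _slow_process(n: int, fs: float, tau_s: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian process with ~tau_s correlation time (AR(1))."""
    a = 1.0 / max(tau_s * fs, 1.0)
    from scipy.signal import lfilter

    z = lfilter([a], [1.0, -(1.0 - a)], rng.standard_normal(n))
    sd = np.std(z)
    return z / sd if sd > 0 else z


def _tone_frequencies(band: tuple[float, float]) -> np.ndarray:
    """One tonal component per 2-Hz analysis bin inside the band.

    The analysis bins are (c-1, c+1] for odd centers c, so the even frequency
    c+1 lies inside bin c and is an exact Fourier frequency of any window
    length that is a multiple of 0.5 s — tone power lands in a single bin
    with no leakage at either the trial or the online segment length.
    """
    lo, hi = band
    centers = np.arange(1, 50, 2)
    centers = centers[(centers >= lo) & (centers <= hi)]
    return (centers + 1.0)[centers + 1.0 <= hi + 1.0]


def _leak_depth(cfg: SynthConfig, labels: list[str]) -> np.ndarray:
    """Per-channel ERD depth: full at source electrodes, distance-decayed nearby."""
    pos = montage_positions()
    depth = np.zeros(len(labels))
    for i, ch in enumerate(labels):
        for src in cfg.erd_channels:
            d = float(np.linalg.norm(pos[ch] - pos[src]))
            if d <= _LEAK_CUTOFF_M:
                depth[i] = max(depth[i], cfg.erd_depth * math.exp(-d / cfg.leak_scale_m))
    return depth


def generate_recording(cfg: SynthConfig) -> Recording:
    """Generate one synthetic training/online recording.

    The cue schedule alternates idle and dorsiflexion epochs of ``epoch_len``
    seconds, starting with idle, ``n_epochs_per_class`` epochs per class.
    Identical configuration (including seed) yields bit-identical output.
    """
    cfg.validate()
    # two random streams: stable subject traits (spectral profiles, rhythm
    # weights and phases, background source geometry) versus per-session
    # realizations (noise, amplitude processes, artifact timing, goniometer);
    # the same subject_seed yields the same "subject" across sessions
    rng = np.random.default_rng(cfg.seed)
    rng_subj = np.random.default_rng(
        cfg.subject_seed if cfg.subject_seed is not None else cfg.seed
    )
    labels = cfg.channel_labels()
    n_epochs = 2 * cfg.n_epochs_per_class
    total_t = n_epochs * cfg.epoch_len
    n_samp = int(round(total_t * cfg.fs_eeg))

    cues = []
    for k in range(n_epochs):
        lab = IDLE if k % 2 == 0 else DORSIFLEX
        cues.append((k * cfg.epoch_len, (k + 1) * cfg.epoch_len, lab))

    # sample mask of dorsiflexion epochs, at the EEG clock
    t_eeg = np.arange(n_samp) / cfg.fs_eeg
    d_mask = np.zeros(n_samp, dtype=bool)
    for start, end, lab in cues:
        if lab == DORSIFLEX:
            d_mask[(t_eeg >= start) & (t_eeg < end)] = True

    f = np.fft.rfftfreq(n_samp, 1.0 / cfg.fs_eeg)
    lo, hi = cfg.erd_band
    band_mask = (f >= lo) & (f <= hi)
    depth = _leak_depth(cfg, labels)

    # which epochs carry artifacts on the hat-band channels
    n_artifact = int(round(cfg.artifact_epoch_frac * n_epochs))
    artifact_epochs = rng.choice(n_epochs, size=n_artifact, replace=False)
    artifact_mask = np.zeros(n_samp, dtype=bool)
    for k in artifact_epochs:
        artifact_mask[(t_eeg >= k * cfg.epoch_len) & (t_eeg < (k + 1) * cfg.epoch_len)] = True
    artifact_set = set(cfg.artifact_channels)

    # shared background sources (volume conduction): each source is a colored
    # noise process at a random scalp location, mixed into channels with a
    # spatially smooth Gaussian gain, so channels are correlated the way real
    # EEG is and a small number of spatial modes carries most of the variance
    pos = montage_positions()
    chan_xyz = np.stack([pos[c] for c in labels])
    src_xyz = chan_xyz[rng_subj.choice(len(labels), size=cfg.n_bg_sources, replace=True)]
    src_params = [_draw_profile_params(rng_subj) for _ in range(cfg.n_bg_sources)]
    sources = np.empty((cfg.n_bg_sources, n_samp))
    for k in range(cfg.n_bg_sources):
        psd = _background_psd_profile(f, *src_params[k])
        sources[k] = np.fft.irfft(np.fft.rfft(rng.standard_normal(n_samp)) * np.sqrt(psd), n_samp)
    dist = np.linalg.norm(chan_xyz[:, None, :] - src_xyz[None, :, :], axis=2)
    mixing = np.exp(-0.5 * (dist / cfg.bg_spatial_scale_m) ** 2)
    shared = mixing @ sources  # (channels, samples)

    # In-band (ERD-band) content is predominantly rhythmic: a bank of tonal
    # components (one per 2-Hz analysis bin, placed on the bin's exact
    # Fourier frequency so binning is leakage-free at both trial and online
    # segment lengths) with slowly drifting scalp-coherent amplitudes, plus a
    # smaller band-limited noise floor.  Oscillations with second-scale
    # envelopes are what make short-segment band-power estimates nearly as
    # reliable as trial-length ones, as they are in real EEG.
    tone_freqs = _tone_frequencies(cfg.erd_band)
    cos_base = np.empty((tone_freqs.size, n_samp))
    sin_base = np.empty((tone_freqs.size, n_samp))
    for m, fm in enumerate(tone_freqs):
        env = np.exp(0.15 * _slow_process(n_samp, cfg.fs_eeg, cfg.rhythm_amp_tau_s, rng))
        cos_base[m] = env * np.cos(2.0 * math.pi * fm * t_eeg)
        sin_base[m] = env * np.sin(2.0 * math.pi * fm * t_eeg)

    # rhythm amplitude variability: EEG rhythms also wax and wane coherently
    # across the scalp (arousal), so the whole in-band component gets a global
    # slowly-varying log-normal amplitude process plus a smaller per-channel
    # process (class-independent); the ERD additionally scales it by
    # sqrt(1 - depth) during dorsiflexion epochs
    z_global = _slow_process(n_samp, cfg.fs_eeg, cfg.rhythm_amp_tau_s, rng)

    chan_params = [_draw_profile_params(rng_subj) for _ in labels]
    tone_mult = np.exp(0.3 * rng_subj.standard_normal((len(labels), tone_freqs.size)))
    tone_phi = rng_subj.uniform(0, 2 * math.pi, (len(labels), tone_freqs.size))

    eeg = np.empty((len(labels), n_samp))
    for i, ch in enumerate(labels):
        psd = _background_psd_profile(f, *chan_params[i])
        beta = float(psd[band_mask].sum() / psd.sum())  # in-band power fraction
        idio = np.fft.irfft(np.fft.rfft(rng.standard_normal(n_samp)) * np.sqrt(psd), n_samp)
        bg = shared[i] / max(np.std(shared[i]), 1e-12) + cfg.idio_frac * idio / max(
            np.std(idio), 1e-12
        )
        spec = np.fft.rfft(bg)
        band_noise = np.fft.irfft(spec * band_mask, n_samp)
        out_part = np.fft.irfft(spec * ~band_mask, n_samp)

        # channel-specific tone weights follow the channel's spectral profile
        w = np.sqrt(np.interp(tone_freqs, f, psd)) * tone_mult[i]
        phi = tone_phi[i]
        bank = (w * np.cos(phi)) @ cos_base + (w * np.sin(phi)) @ sin_base
        in_part = math.sqrt(1.0 - cfg.osc_frac) * band_noise / max(np.std(band_noise), 1e-12)
        in_part = in_part + math.sqrt(cfg.osc_frac) * bank / max(np.std(bank), 1e-12)

        z_local = _slow_process(n_samp, cfg.fs_eeg, cfg.rhythm_amp_tau_s, rng)
        gain = np.exp(
            cfg.rhythm_amp_jitter * z_global + cfg.rhythm_amp_jitter_local * z_local
        )
        if depth[i] > 0:
            gain = gain * np.where(d_mask, math.sqrt(1.0 - depth[i]), 1.0)
        composite = math.sqrt(1.0 - beta) * out_part / max(np.std(out_part), 1e-12)
        composite = composite + math.sqrt(beta) * gain * in_part / max(np.std(in_part), 1e-12)
        sig = composite * (10.0 / max(np.std(composite), 1e-12))  # ~10 uV RMS
        if ch in artifact_set and cfg.artifact_gain > 1.0:
            sig[artifact_mask] *= cfg.artifact_gain
        eeg[i] = sig

    # goniometer traces: row 0 voluntary ankle, row 1 contralateral (FES) ankle
    n_gon = int(round(total_t * cfg.fs_gonio))
    t_gon = np.arange(n_gon) / cfg.fs_gonio
    gonio = rng.normal(0.0, 0.3, size=(2, n_gon))
    for start, end, lab in cues:
        if lab != DORSIFLEX:
            continue
        sel = (t_gon >= start) & (t_gon < end)
        # a whole number of cycles per epoch, so the ankle returns to rest at
        # the cue boundary (the task is "repeat N full dorsiflexion cycles")
        n_cycles = max(1, round(cfg.dorsiflexion_rate * (end - start)))
        phase = 2.0 * math.pi * n_cycles * (t_gon[sel] - start) / (end - start)
        gonio[0, sel] += 0.5 * cfg.dorsiflexion_amp_deg * (1.0 - np.cos(phase))

    rec = Recording(
        eeg=eeg,
        fs_eeg=cfg.fs_eeg,
        channel_labels=labels,
        goniometer=gonio,
        fs_gonio=cfg.fs_gonio,
        cue_schedule=cues,
    )
    rec.validate()
    return rec


def generate_decision_stream(n_steps: int, p_dorsi: float, seed: int) -> np.ndarray:
    """Independent chance-level class decisions, one per 0.5-s decoder step.

    Returns an array of "I"/"D" labels; reproducible under ``seed``.
    """
    if n_steps <= 0:
        raise ConfigError("n_steps must be positive")
    if not (0.0 <= p_dorsi <= 1.0):
        raise ConfigError("p_dorsi must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    draws = rng.random(n_steps) < p_dorsi
    return np.where(draws, DORSIFLEX, IDLE)
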