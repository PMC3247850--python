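"""Binned power-spectral-density features and the class-contrast SNR spectrum.

Each trial is transformed with a plain (rectangular-window) FFT periodogram and
the one-sided PSD is integrated in 2-Hz bins centered at 1, 3, ..., 49 Hz; a
bin centered at c covers the half-open interval (c-1, c+1], so the 25 bins are
disjoint and complete over (0, 50] and DC is excluded.  Integrated power (PSD
density summed times the frequency step) is duration-invariant in expectation,
which keeps 6-s training epochs and 0.5-s online segments on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .exceptions import ConfigError, DataError
from .preprocess import EpochSet

__all__ = [
    "FULL_BAND",
    "log_power",
    "bin_centers_in_band",
    "binned_psd",
    "SpectralTrials",
    "spectral_trials",
    "snr_spectrum",
]

FULL_BAND = (0.01, 50.0)
_ALL_CENTERS = np.arange(1, 50, 2)  # 1, 3, ..., 49 Hz


def log_power(x: np.ndarray) -> np.ndarray:
    """Elementwise log of non-negative power values, floored to stay finite."""
    return np.log(np.maximum(np.asarray(x, dtype=float), 1e-30))


def bin_centers_in_band(band: tuple[float, float]) -> np.ndarray:
    """The odd-integer bin centers (Hz) lying inside [F_L, F_H]."""
    lo, hi = band
    centers = _ALL_CENTERS[(_ALL_CENTERS >= lo) & (_ALL_CENTERS <= hi)]
    if centers.size == 0:
        raise ConfigError(f"band {band} contains no PSD bin centers")
    return centers


def binned_psd(
    trial: np.ndarray, fs: float, band: tuple[float, float] = FULL_BAND
) -> np.ndarray:
    """Integrated 2-Hz-binned PSD per channel.

    Parameters
    ----------
    trial : (channels, samples) array, at least 0.5 s of data
    fs : sampling rate in Hz
    band : [F_L, F_H]; only bins whose centers lie inside are returned

    Returns
    -------
    (n_bins, channels) array of integrated power (microvolt^2) per bin; the
    full 0.01-50 Hz band yields 25 values per channel.
    """
    trial = np.atleast_2d(np.asarray(trial, dtype=float))
    n = trial.shape[-1]
    if n < fs / 2:
        raise DataError("trial shorter than 0.5 s")
    centers = bin_centers_in_band(band)
    freqs, psd = signal.periodogram(trial, fs=fs, window="boxcar", axis=-1)
    df = freqs[1] - freqs[0]
    out = np.empty((centers.size, trial.shape[0]))
    for i, c in enumerate(centers):
        sel = (freqs > c - 1.0) & (freqs <= c + 1.0)
        out[i] = psd[:, sel].sum(axis=-1) * df
    return out


@dataclass
class SpectralTrials:
    """Binned spectral power for a set of trials over the retained channels."""

    power: np.ndarray  # (trials, bins, channels), integrated microvolt^2
    bin_centers: np.ndarray  # (bins,) Hz
    channel_labels: list[str]
    band: tuple[float, float]
    labels: np.ndarray  # (trials,) of "I"/"D"

    def validate(self) -> None:
        if self.power.ndim != 3:
            raise DataError("power must be trials x bins x channels")
        if np.any(self.power < 0):
            raise DataError("spectral power must be non-negative")
        if self.power.shape[1] != self.bin_centers.size:
            raise DataError("bin_centers length mismatch")
        if self.power.shape[2] != len(self.channel_labels):
            raise DataError("channel_labels length mismatch")

    @property
    def matrix(self) -> np.ndarray:
        """Trials x (bins * channels) raw-power matrix (bins vary fastest)."""
        return self.power.reshape(self.power.shape[0], -1)

    def features(self) -> np.ndarray:
        """Classifier-facing feature matrix: log band power.

        The log stabilizes the variance of the power estimates (raw binned
        power is approximately scaled chi-squared, so its variance grows with
        its mean and low-frequency bins dominate any variance-based
        subspace); log band power is the standard EEG decoding
        representation.  Same transform at training and online time.
        """
        return log_power(self.matrix)

    def restrict(self, band: tuple[float, float]) -> "SpectralTrials":
        """Restrict to the bins whose centers lie inside ``band``."""
        centers = bin_centers_in_band(band)
        sel = np.isin(self.bin_centers, centers)
        return SpectralTrials(
            power=self.power[:, sel, :],
            bin_centers=self.bin_centers[sel],
            channel_labels=list(self.channel_labels),
            band=band,
            labels=self.labels,
        )


def spectral_trials(
    epochs: EpochSet, band: tuple[float, float] = FULL_BAND
) -> SpectralTrials:
    """Binned PSD features for every trial, retained channels only."""
    data = epochs.retained_data()
    centers = bin_centers_in_band(band)
    power = np.empty((epochs.n_trials, centers.size, data.shape[1]))
    for t in range(epochs.n_trials):
        power[t] = binned_psd(data[t], epochs.fs, band)
    st = SpectralTrials(
        power=power,
        bin_centers=centers,
        channel_labels=epochs.retained_labels(),
        band=band,
        labels=np.asarray(epochs.labels),
    )
    st.validate()
    return st


def snr_spectrum(
    power_idle: np.ndarray, power_dorsi: np.ndarray, alpha: float = 0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin class-contrast SNR and paired-t significance mask.

    SNR(f) = (mu_i(f) - mu_d(f))^2 / (sigma_i^2(f) + sigma_d^2(f)) over trials;
    bins with zero variance in both classes are reported as NaN.  The mask
    marks bins whose paired t-test p-value is below ``alpha`` (trial counts
    must match across classes for the pairing).
    """
    pi = np.asarray(power_idle, dtype=float)
    pd_ = np.asarray(power_dorsi, dtype=float)
    if pi.shape != pd_.shape:
        raise DataError("paired SNR requires equal trial counts per class")
    if pi.shape[0] < 2:
        raise DataError("need >= 2 trials per class")
    mu_i, mu_d = pi.mean(axis=0), pd_.mean(axis=0)
    var_i, var_d = pi.var(axis=0, ddof=1), pd_.var(axis=0, ddof=1)
    denom = var_i + var_d
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(denom > 0, (mu_i - mu_d) ** 2 / np.maximum(denom, 1e-300), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        _, pval = stats.ttest_rel(pi, pd_, axis=0)
    mask = np.nan_to_num(pval, nan=1.0) < alpha
    return snr, mask
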