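"""Performance analysis of an online run and the Monte Carlo chance null.

The voluntary and decoder-mediated movement traces are smoothed, binarized by
threshold crossing, and compared through the normalized cross-covariance

    rho(m) = sum_i (x[i-m] - xbar)(y[i] - ybar)
             / sqrt( sum_i (x[i] - xbar)^2 * sum_i (y[i] - ybar)^2 )

with full-series means and sums in the normalization and out-of-range terms
contributing zero.  The lag axis is oriented so that a positive best lag m*
means the response follows the voluntary trace.  Omissions (voluntary epochs
with no decoder-initiated response) and false alarms (initiations inside an
idle epoch) are counted from response initiations (0 -> 1 transitions) against
the cue schedule.

The chance null replaces the classifier output with Bernoulli(0.5) decisions
at 2 per second, runs them through the same averaging + hysteresis machine,
and measures rho* per trial.  Because both timelines are piecewise constant on
0.5-s blocks, rho(m) is piecewise linear in the lag with knots on the 0.5-s
grid, so evaluating on the decision clock recovers the exact maximum at a
fraction of the cost of a resampled computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .exceptions import ConfigError, DataError
from .selection import Thresholds
from .synth import DORSIFLEX, IDLE

__all__ = [
    "BinaryTimeline",
    "PerformanceReport",
    "binarize_goniometer",
    "resample_binary",
    "cross_covariance_report",
    "count_events",
    "monte_carlo_chance",
    "MonteCarloNull",
    "default_online_cues",
]


@dataclass
class BinaryTimeline:
    """A strictly binary 0/1 time series at a fixed sampling rate."""

    values: np.ndarray
    fs: float

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.size < 2:
            raise DataError("timeline needs at least 2 samples")
        if not np.isin(self.values, (0, 1)).all():
            raise DataError("timeline values must be strictly 0/1")
        self.values = self.values.astype(np.int8)

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class PerformanceReport:
    """Summary of one online session."""

    lag_s: float
    rho_star: float
    omissions: int
    false_alarms: int
    lags: np.ndarray  # lag axis in samples
    rho_curve: np.ndarray


def binarize_goniometer(
    trace: np.ndarray, fs: float, threshold: float, smooth_ms: float = 100.0
) -> BinaryTimeline:
    """Gaussian-smooth an angle trace and threshold it into a 0/1 timeline.

    The smoothing kernel's total width is ``smooth_ms`` with SD = width/6, so
    >= 99.7% of its mass lies inside the stated window.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.isfinite(trace).all():
        raise DataError("goniometer trace contains non-finite samples")
    if fs <= 0:
        raise ConfigError("fs must be positive")
    sigma = (smooth_ms / 1000.0) * fs / 6.0
    smoothed = gaussian_filter1d(trace, sigma) if sigma > 0 else trace
    return BinaryTimeline(values=(smoothed > threshold).astype(np.int8), fs=fs)


def resample_binary(tl: BinaryTimeline, fs_target: float) -> BinaryTimeline:
    """Nearest-sample resampling of a binary timeline to a common clock."""
    if np.isclose(tl.fs, fs_target):
        return tl
    n_out = int(round(tl.n * fs_target / tl.fs))
    idx = np.minimum((np.arange(n_out) * tl.fs / fs_target).astype(int), tl.n - 1)
    return BinaryTimeline(values=tl.values[idx], fs=fs_target)


def _rho_curve(xc: np.ndarray, yc: np.ndarray, lags: np.ndarray, denom: float) -> np.ndarray:
    n = xc.size
    out = np.empty(lags.size)
    for i, m in enumerate(lags):
        if m >= 0:
            num = float(xc[: n - m] @ yc[m:]) if m < n else 0.0
        else:
            num = float(xc[-m:] @ yc[: n + m]) if -m < n else 0.0
        out[i] = num / denom
    return out


def cross_covariance_report(
    x: BinaryTimeline, y: BinaryTimeline, max_lag: float | None = 5.0
) -> tuple[np.ndarray, int, float]:
    """Normalized cross-covariance over lags |m| <= max_lag * fs.

    Returns (rho_curve, m_star, rho_star); m_star is in samples, positive when
    ``y`` lags ``x``.  A tie at the maximum resolves to the smallest |m|;
    ``max_lag=None`` searches the full lag domain.
    """
    if not np.isclose(x.fs, y.fs):
        raise DataError("timelines must share a sampling rate")
    n = min(x.n, y.n)
    xv, yv = x.values[:n].astype(float), y.values[:n].astype(float)
    xc, yc = xv - xv.mean(), yv - yv.mean()
    sx, sy = float(xc @ xc), float(yc @ yc)
    for name, s in (("x", sx), ("y", sy)):
        if s <= 0:
            raise DataError(f"series {name} is constant; cross-covariance undefined")
    denom = np.sqrt(sx * sy)
    max_m = n - 1 if max_lag is None else min(int(round(max_lag * x.fs)), n - 1)
    lags = np.arange(-max_m, max_m + 1)
    rho = _rho_curve(xc, yc, lags, denom)
    # tie at the max -> smallest |m| (then the earlier, negative lag)
    order = np.lexsort((lags, np.abs(lags)))
    ordered_rho = rho[order]
    best_pos = int(np.argmax(ordered_rho))
    m_star = int(lags[order][best_pos])
    return rho, m_star, float(ordered_rho[best_pos])


def _initiations(y: np.ndarray) -> np.ndarray:
    """Indices where a response epoch initiates (0 -> 1, including t = 0)."""
    prev = np.concatenate(([0], y[:-1]))
    return np.flatnonzero((y == 1) & (prev == 0))


def count_events(
    x: BinaryTimeline,
    y: BinaryTimeline,
    cue_schedule: list[tuple[float, float, str]],
) -> tuple[int, int]:
    """Count omissions and false alarms of the response ``y``.

    An omission is a voluntary-dorsiflexion cue interval containing no
    response initiation; a false alarm is a response initiation inside an
    idling interval.  Only initiations matter — response epoch durations are
    irrelevant.
    """
    if not np.isclose(x.fs, y.fs):
        raise DataError("timelines must share a sampling rate")
    prev_end = -np.inf
    for start, end, _ in cue_schedule:
        if start < prev_end:
            raise DataError("overlapping cue intervals")
        prev_end = end
    init_t = _initiations(y.values) / y.fs
    omissions = 0
    false_alarms = 0
    for start, end, lab in cue_schedule:
        inside = (init_t >= start) & (init_t < end)
        if lab == DORSIFLEX and not inside.any():
            omissions += 1
        elif lab == IDLE:
            false_alarms += int(inside.sum())
    return omissions, false_alarms


def evaluate_run(
    voluntary_trace: np.ndarray,
    fs_voluntary: float,
    response_trace: np.ndarray,
    fs_response: float,
    cue_schedule: list[tuple[float, float, str]],
    threshold_deg: float = 5.0,
    common_fs: float = 256.0,
    max_lag: float = 5.0,
) -> PerformanceReport:
    """Full performance report: binarize both traces, correlate, count events.

    Both goniometer traces are smoothed/binarized and resampled to a common
    clock before the cross-covariance; the statistics are rate-invariant after
    smoothing.
    """
    x = resample_binary(binarize_goniometer(voluntary_trace, fs_voluntary, threshold_deg), common_fs)
    y = resample_binary(binarize_goniometer(response_trace, fs_response, threshold_deg), common_fs)
    n = min(x.n, y.n)
    x = BinaryTimeline(x.values[:n], common_fs)
    y = BinaryTimeline(y.values[:n], common_fs)
    rho, m_star, rho_star = cross_covariance_report(x, y, max_lag=max_lag)
    omissions, false_alarms = count_events(x, y, cue_schedule)
    max_m = (rho.size - 1) // 2
    return PerformanceReport(
        lag_s=m_star / common_fs,
        rho_star=rho_star,
        omissions=omissions,
        false_alarms=false_alarms,
        lags=np.arange(-max_m, max_m + 1),
        rho_curve=rho,
    )


def default_online_cues(
    n_pairs: int = 10, epoch_len: float = 10.0
) -> list[tuple[float, float, str]]:
    """The standard online protocol: alternating idle/dorsiflexion epochs."""
    cues = []
    for k in range(2 * n_pairs):
        lab = IDLE if k % 2 == 0 else DORSIFLEX
        cues.append((k * epoch_len, (k + 1) * epoch_len, lab))
    return cues


@dataclass
class MonteCarloNull:
    """Distribution of rho* under chance-level decoding."""

    max_rho: float
    rho: np.ndarray  # per-trial rho*
    n_trials: int


def _chance_fsm(p: np.ndarray, t1: float, t2: float, k: int) -> np.ndarray:
    """Vectorized hysteresis machine over (trials, steps) posterior streams.

    Matches :func:`bcifes.online.decoder_step` exactly: startup averages the
    available values, strict inequalities, initial state idle.
    """
    n_trials, n_steps = p.shape
    csum = np.cumsum(p, axis=1)
    p_bar = np.empty_like(p, dtype=float)
    for j in range(n_steps):
        lo = max(0, j - k + 1)
        width = j - lo + 1
        p_bar[:, j] = (csum[:, j] - (csum[:, lo - 1] if lo > 0 else 0.0)) / width
    y = np.empty((n_trials, n_steps), dtype=np.int8)
    cur = np.zeros(n_trials, dtype=bool)
    for j in range(n_steps):
        trig = p_bar[:, j] > t1
        rel = p_bar[:, j] < t2
        cur = np.where(cur, ~rel, trig)
        y[:, j] = cur
    return y


def monte_carlo_chance(
    cue_schedule: list[tuple[float, float, str]] | None = None,
    thresholds: Thresholds | None = None,
    n_trials: int = 10_000,
    seed: int = 0,
    fs_decisions: float = 2.0,
    averaging_window: float = 1.5,
    max_lag: float | None = None,
    bypass_averaging: bool = False,
) -> MonteCarloNull:
    """Chance-level null distribution of the temporal correlation rho*.

    Per trial, chance decisions (Bernoulli 0.5 per 0.5-s step, injected as the
    classifier's per-step label, P(D) in {0, 1}) pass through the averaging +
    hysteresis machine with the session thresholds (default T1 = T2 = 0.5);
    the resulting response timeline is correlated against the voluntary
    timeline derived from the cue schedule.  Trials whose response timeline is
    constant receive rho* = 0 by convention, so the loop never aborts.
    ``bypass_averaging=True`` feeds the raw decisions to the state machine
    without the 1.5-s moving average.  The lag search spans the full lag
    domain by default (``max_lag=None``), matching the definition of the
    best-lag correlation; the full-series normalization shrinks extreme lags,
    so distant spurious maxima are already penalized.
    """
    if n_trials < 1:
        raise ConfigError("n_trials must be >= 1")
    cues = cue_schedule if cue_schedule is not None else default_online_cues()
    thr = thresholds if thresholds is not None else Thresholds(T1=0.5, T2=0.5)
    duration = max(end for _, end, _ in cues)
    n_steps = int(round(duration * fs_decisions))
    t_step = np.arange(n_steps) / fs_decisions
    x = np.zeros(n_steps, dtype=np.int8)
    for start, end, lab in cues:
        if lab == DORSIFLEX:
            x[(t_step >= start) & (t_step < end)] = 1
    if x.sum() in (0, n_steps):
        raise DataError("cue schedule yields a constant voluntary timeline")

    rng = np.random.default_rng(seed)
    p = (rng.random((n_trials, n_steps)) < 0.5).astype(float)
    k = 1 if bypass_averaging else max(1, int(round(averaging_window * fs_decisions)))
    y = _chance_fsm(p, thr.T1, thr.T2, k)

    xc = x.astype(float) - x.mean()
    yc = y.astype(float) - y.mean(axis=1, keepdims=True)
    sx = float(xc @ xc)
    sy = (yc * yc).sum(axis=1)
    max_m = (
        n_steps - 1
        if max_lag is None
        else min(int(round(max_lag * fs_decisions)), n_steps - 1)
    )
    lags = np.arange(-max_m, max_m + 1)
    num = np.empty((n_trials, lags.size))
    for i, m in enumerate(lags):
        if m >= 0:
            num[:, i] = yc[:, m:] @ xc[: n_steps - m]
        else:
            num[:, i] = yc[:, : n_steps + m] @ xc[-m:]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = num / np.sqrt(sx * sy)[:, None]
    best = np.where(np.isfinite(rho), rho, -np.inf).max(axis=1)
    rho_star = np.where(sy > 0, best, 0.0)
    return MonteCarloNull(max_rho=float(rho_star.max()), rho=rho_star, n_trials=n_trials)
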