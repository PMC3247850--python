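"""Cross-validation, greedy frequency-band search, chance-level significance,
and posterior-threshold calibration.

The band search mirrors the training recipe: starting from the full 0.01-50 Hz
range, the lower bound F_L rises in 2-Hz steps while the cross-validated
accuracy strictly improves (a tie stops the search — the smaller model wins);
the upper bound F_H then descends the same way.  Fold assignments are fixed
across candidate bands so candidates are compared on identical splits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.model_selection import StratifiedKFold

from .decode import (
    FeatureExtractor,
    GaussianPieceModel,
    classify,
    extract_feature,
    fit_classifier,
    fit_extractor,
)
from .exceptions import ConfigError, DataError
from .preprocess import EpochSet
from .spectral import FULL_BAND, SpectralTrials, bin_centers_in_band, spectral_trials
from .synth import DORSIFLEX, IDLE

__all__ = [
    "PredictionModel",
    "Thresholds",
    "crossvalidate",
    "search_frequency_band",
    "chance_tail_probability",
    "estimate_thresholds",
]

logger = logging.getLogger(__name__)


@dataclass
class PredictionModel:
    """Everything the online decoder needs: channels, band, maps, classifier."""

    channel_labels: list[str]  # retained channels, montage order
    band: tuple[float, float]  # [F_L, F_H] on 2-Hz bin edges
    extractor: FeatureExtractor
    classifier: GaussianPieceModel
    cv_accuracy: float
    fs: float = 256.0
    variance_kept: float = 0.95
    method: str = "lda"
    train_seg_len_s: float = 6.0  # trial length the classifier was fit on
    search_trail: list[tuple[tuple[float, float], float, bool]] = field(default_factory=list)

    def validate(self) -> None:
        if not self.channel_labels:
            raise DataError("prediction model retains no channels")
        lo, hi = self.band
        if not lo < hi:
            raise DataError("band must satisfy F_L < F_H")
        if not (0.0 <= self.cv_accuracy <= 1.0):
            raise DataError("cv_accuracy must lie in [0, 1]")
        bin_centers_in_band(self.band)


@dataclass
class Thresholds:
    """Hysteresis pair on the posterior-probability scale.

    T1 governs idle -> dorsiflexion (trigger when the averaged P(D) exceeds
    T1), T2 dorsiflexion -> idle (release when it falls below T2).
    """

    T1: float
    T2: float
    quartiles: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for name, v in (("T1", self.T1), ("T2", self.T2)):
            if not (0.0 <= v <= 1.0):
                raise DataError(f"{name} must lie in [0, 1]")
        if self.T1 <= self.T2:
            logger.warning("degenerate calibration: T1=%.3f <= T2=%.3f", self.T1, self.T2)


def _fit_predict(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    variance_kept: float,
    method: str,
) -> np.ndarray:
    ext = fit_extractor(x_train, y_train, variance_kept=variance_kept, method=method)
    model = fit_classifier(extract_feature(ext, x_train), y_train)
    return classify(model, extract_feature(ext, x_test))


def crossvalidate(
    spectra: SpectralTrials | np.ndarray,
    labels: np.ndarray | None = None,
    folds: int = 10,
    runs: int = 5,
    seed: int = 0,
    variance_kept: float = 0.95,
    method: str = "lda",
) -> tuple[float, pd.DataFrame]:
    """Repeated stratified k-fold accuracy of the extractor + classifier.

    The extractor and classifier are refit inside every training fold (no
    leakage).  Returns the mean correct fraction over runs x folds and the
    per-fold table (columns run, fold, n_test, accuracy); reproducible under
    ``seed``.
    """
    if isinstance(spectra, SpectralTrials):
        x = spectra.features()
        labels = spectra.labels if labels is None else np.asarray(labels)
    else:
        x = np.asarray(spectra, dtype=float)
        if labels is None:
            raise ConfigError("labels required when passing a raw feature matrix")
        labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if np.any(counts < folds):
        raise DataError(f"every class needs >= {folds} trials for {folds}-fold CV")

    rows = []
    for run in range(runs):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + 1000 * run)
        for fold, (tr, te) in enumerate(skf.split(x, labels)):
            pred = _fit_predict(x[tr], labels[tr], x[te], variance_kept, method)
            rows.append(
                {
                    "run": run,
                    "fold": fold,
                    "n_test": len(te),
                    "accuracy": float((pred == labels[te]).mean()),
                }
            )
    table = pd.DataFrame(rows)
    return float(table["accuracy"].mean()), table


def search_frequency_band(
    epochs: EpochSet,
    folds: int = 10,
    runs: int = 5,
    seed: int = 0,
    variance_kept: float = 0.95,
    method: str = "lda",
) -> PredictionModel:
    """Greedy 2-Hz band search, then refit on all data at the optimal band.

    Starting from the full band, F_L rises in 2-Hz steps while the CV
    accuracy strictly improves; F_H then descends likewise.  The audit trail
    of (band, accuracy, accepted) is kept on the returned model.
    """
    full = spectral_trials(epochs, FULL_BAND)
    labels = full.labels

    def acc_for(band: tuple[float, float]) -> float:
        a, _ = crossvalidate(
            full.restrict(band), folds=folds, runs=runs, seed=seed,
            variance_kept=variance_kept, method=method,
        )
        return a

    f_l, f_h = 0.0, 50.0
    trail: list[tuple[tuple[float, float], float, bool]] = []
    best = acc_for((f_l, f_h))
    trail.append(((f_l, f_h), best, True))

    while True:
        cand = (f_l + 2.0, f_h)
        if cand[0] >= cand[1] or bin_centers_in_band(cand).size < 1:
            break
        a = acc_for(cand)
        improved = a > best
        trail.append((cand, a, improved))
        logger.info("band search F_L: %s acc=%.4f %s", cand, a, "accept" if improved else "stop")
        if not improved:
            break
        f_l, best = cand[0], a

    while True:
        cand = (f_l, f_h - 2.0)
        if cand[0] >= cand[1]:
            break
        try:
            if bin_centers_in_band(cand).size < 1:
                break
        except ConfigError:
            break
        a = acc_for(cand)
        improved = a > best
        trail.append((cand, a, improved))
        logger.info("band search F_H: %s acc=%.4f %s", cand, a, "accept" if improved else "stop")
        if not improved:
            break
        f_h, best = cand[1], a

    band = (f_l, f_h)
    st = full.restrict(band)
    ext = fit_extractor(st.features(), labels, variance_kept=variance_kept, method=method)
    clf = fit_classifier(extract_feature(ext, st.features()), labels)
    model = PredictionModel(
        channel_labels=list(st.channel_labels),
        band=band,
        extractor=ext,
        classifier=clf,
        cv_accuracy=best,
        fs=epochs.fs,
        variance_kept=variance_kept,
        method=method,
        search_trail=trail,
        train_seg_len_s=epochs.data.shape[2] / epochs.fs,
    )
    model.validate()
    return model


def chance_tail_probability(
    n_correct: int, n_total: int, p: float = 0.5, return_log: bool = False
) -> float:
    """Exact binomial upper tail P(X >= n_correct | n_total, p), in log space.

    Quantifies how likely a chance-level classifier is to reach a given
    accuracy; e.g. 170 or more correct out of 200 at p = 0.5 has probability
    ~3.09e-25.  ``return_log=True`` yields the natural log, which survives
    below the smallest positive float.
    """
    if not (0 <= n_correct <= n_total):
        raise ConfigError("need 0 <= n_correct <= n_total")
    if not (0.0 <= p <= 1.0):
        raise ConfigError("p must lie in [0, 1]")
    if n_correct == 0:  # whole sample space
        return 0.0 if return_log else 1.0
    k = np.arange(n_correct, n_total + 1)
    log_tail = float(logsumexp(stats.binom.logpmf(k, n_total, p)))
    log_tail = min(log_tail, 0.0)  # guard rounding above 1
    return log_tail if return_log else float(np.exp(log_tail))


def estimate_thresholds(
    posterior_stream: np.ndarray, true_state: np.ndarray
) -> Thresholds:
    """Calibration medians of the per-step posterior P(D).

    T1 = median over steps whose true state is dorsiflexion, T2 = median over
    idle steps; the 25/50/75% quartiles of both empirical distributions are
    reported alongside.
    """
    p = np.asarray(posterior_stream, dtype=float)
    s = np.asarray(true_state)
    quartiles = {}
    for c in (IDLE, DORSIFLEX):
        pc = p[s == c]
        if pc.size == 0:
            raise DataError(f"state {c} absent from the calibration stream")
        quartiles[c] = tuple(float(q) for q in np.percentile(pc, [25, 50, 75]))
    thr = Thresholds(T1=quartiles[DORSIFLEX][1], T2=quartiles[IDLE][1], quartiles=quartiles)
    thr.validate()
    return thr
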