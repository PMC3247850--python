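"""Piecewise-linear feature extraction and Bayesian posterior classification.

Dimensionality reduction is classwise: each class gets its own principal
subspace (retaining a set fraction of that class's variance), and within each
subspace a supervised linear map sends the projected trials to a single scalar
feature.  The default 1-D map is the Fisher linear discriminant direction; an
approximate information discriminant (gradient ascent on a Gaussian-entropy
mutual-information surrogate) is available behind the same interface.  The
classifier models the scalar feature of each piece with one 1-D Gaussian per
class; posteriors follow from Bayes' rule, and the piece whose marginal
evidence is larger supplies the final posterior (the standard classwise-PCA
classification rule).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigError, DataError
from .synth import DORSIFLEX, IDLE

__all__ = [
    "CLASSES",
    "FeatureExtractor",
    "GaussianPieceModel",
    "fit_extractor",
    "extract_feature",
    "fit_classifier",
    "posterior",
    "classify",
]

CLASSES = (IDLE, DORSIFLEX)


@dataclass
class FeatureExtractor:
    """Per-class principal bases and 1-D discriminant vectors.

    For piece ``c`` the scalar feature of a trial vector ``d`` is
    ``w_c . (U_c^T (d - mu_c))`` with orthonormal basis ``U_c``, class center
    ``mu_c`` and unit-norm discriminant ``w_c``.
    """

    centers: dict[str, np.ndarray]  # class -> (p,)
    bases: dict[str, np.ndarray]  # class -> (p, m_c), orthonormal columns
    discriminants: dict[str, np.ndarray]  # class -> (m_c,), unit norm
    n_features: int = 0

    def validate(self) -> None:
        for c in CLASSES:
            u, w = self.bases[c], self.discriminants[c]
            if u.shape[1] < 1:
                raise DataError(f"piece {c} has empty basis")
            if not np.allclose(u.T @ u, np.eye(u.shape[1]), atol=1e-8):
                raise DataError(f"piece {c} basis is not orthonormal")
            if not np.isclose(np.linalg.norm(w), 1.0, atol=1e-8):
                raise DataError(f"piece {c} discriminant is not unit norm")

    def composed_map(self, piece: str) -> tuple[np.ndarray, np.ndarray]:
        """The feature of piece ``c`` as one affine map: (vector a, center mu)."""
        return self.bases[piece] @ self.discriminants[piece], self.centers[piece]


def _class_pca(x: np.ndarray, variance_kept: float) -> tuple[np.ndarray, np.ndarray]:
    """Principal basis of one class's trials retaining >= variance_kept."""
    mu = x.mean(axis=0)
    xc = x - mu
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        raise DataError("zero-variance class data: cannot fit a principal basis")
    rank = int((s > s[0] * 1e-10).sum())
    cum = np.cumsum(var) / total
    m = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    m = max(1, min(m, rank))
    basis = vt[:m].T  # (p, m)
    # sign convention: largest-magnitude loading of each component is positive
    for j in range(m):
        k = np.argmax(np.abs(basis[:, j]))
        if basis[k, j] < 0:
            basis[:, j] = -basis[:, j]
    return mu, basis


def _fisher_direction(z: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Fisher discriminant direction in the subspace.

    The within-class covariance is regularized with Ledoit-Wolf shrinkage
    toward a scaled identity: with ~100 trials in a subspace of comparable
    dimension the sample covariance is badly conditioned, and the shrunk
    estimator interpolates between the whitened Fisher direction and the
    plain class-mean difference as the data demand.
    """
    zi, zd = z[labels == IDLE], z[labels == DORSIFLEX]
    mi, md = zi.mean(axis=0), zd.mean(axis=0)
    if z.shape[1] == 1:
        return np.ones(1)
    resid = np.vstack([zi - mi, zd - md])
    from sklearn.covariance import ledoit_wolf

    sw, _ = ledoit_wolf(resid, assume_centered=True)
    sw = sw + np.eye(sw.shape[0]) * (1e-12 * max(np.trace(sw) / sw.shape[0], 1e-30))
    w = np.linalg.solve(sw, md - mi)
    nrm = np.linalg.norm(w)
    if nrm <= 0:
        w = np.zeros(z.shape[1])
        w[0] = 1.0
        return w
    return w / nrm


def _aida_direction(z: np.ndarray, labels: np.ndarray, n_iter: int = 200, lr: float = 0.1) -> np.ndarray:
    """Approximate information discriminant: ascend a Gaussian-entropy
    mutual-information surrogate J(w) = 1/2 [log w'St w - sum_c pi_c log w'Sc w],
    initialized at the Fisher direction."""
    w = _fisher_direction(z, labels)
    st = np.atleast_2d(np.cov(z, rowvar=False, ddof=1))
    covs, priors = [], []
    for c in CLASSES:
        zc = z[labels == c]
        covs.append(np.atleast_2d(np.cov(zc, rowvar=False, ddof=1)))
        priors.append(len(zc) / len(z))
    eye = np.eye(st.shape[0])
    st = st + eye * 1e-12
    covs = [c + eye * 1e-12 for c in covs]
    for _ in range(n_iter):
        grad = (st @ w) / (w @ st @ w)
        for pc, sc in zip(priors, covs):
            grad = grad - pc * (sc @ w) / (w @ sc @ w)
        w_new = w + lr * grad
        w_new /= np.linalg.norm(w_new)
        if np.linalg.norm(w_new - w) < 1e-10:
            w = w_new
            break
        w = w_new
    # orient toward the dorsiflexion class mean
    md = z[labels == DORSIFLEX].mean(axis=0) - z[labels == IDLE].mean(axis=0)
    if w @ md < 0:
        w = -w
    return w


def fit_extractor(
    x: np.ndarray,
    labels: np.ndarray,
    variance_kept: float = 0.95,
    method: str = "lda",
) -> FeatureExtractor:
    """Fit the piecewise feature extractor on trials x features data.

    For each class, the principal components of that class's trials retaining
    at least ``variance_kept`` of its variance form the basis; all trials are
    then projected into each class subspace and a supervised 1-D direction is
    fit there (``method="lda"`` Fisher closed form, ``"aida"`` approximate
    information maximizer).  Deterministic; basis signs are fixed by making
    the largest-magnitude loading of each component positive, discriminants
    point toward the dorsiflexion class mean.
    """
    if not (0.0 < variance_kept <= 1.0):
        raise ConfigError("variance_kept must lie in (0, 1]")
    if method not in ("lda", "aida"):
        raise ConfigError(f"unknown discriminant method {method!r}")
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    centers, bases, discs = {}, {}, {}
    for c in CLASSES:
        xc = x[labels == c]
        if len(xc) < 2:
            raise DataError(f"need >= 2 trials of class {c}")
        mu, basis = _class_pca(xc, variance_kept)
        z = (x - mu) @ basis
        w = _fisher_direction(z, labels) if method == "lda" else _aida_direction(z, labels)
        if w @ (z[labels == DORSIFLEX].mean(axis=0) - z[labels == IDLE].mean(axis=0)) < 0:
            w = -w
        centers[c], bases[c], discs[c] = mu, basis, w
    ext = FeatureExtractor(centers=centers, bases=bases, discriminants=discs, n_features=x.shape[1])
    ext.validate()
    return ext


def extract_feature(ext: FeatureExtractor, d: np.ndarray) -> np.ndarray:
    """Scalar feature in each class subspace.

    ``d`` may be a single feature vector or an (n, p) stack; returns an array
    of shape (2,) or (n, 2) ordered (idle piece, dorsiflexion piece).
    """
    d = np.asarray(d, dtype=float)
    single = d.ndim == 1
    d2 = np.atleast_2d(d)
    if d2.shape[1] != ext.n_features:
        raise DataError(f"feature dimension {d2.shape[1]} != extractor {ext.n_features}")
    cols = []
    for c in CLASSES:
        a, mu = ext.composed_map(c)
        cols.append((d2 - mu) @ a)
    out = np.stack(cols, axis=1)
    return out[0] if single else out


@dataclass
class GaussianPieceModel:
    """Gaussian class-conditional densities of the piece features.

    Per piece and class, the 1-D mean and variance of that piece's scalar
    feature; per class, additionally the cross-covariance between the two
    piece features.  The two features are linear views of the same trial and
    are strongly correlated, so the posterior treats them as one bivariate
    Gaussian observation per class — ignoring the correlation would double-
    count the evidence and saturate the posteriors.
    """

    means: dict[str, dict[str, float]]  # piece -> class -> mean
    variances: dict[str, dict[str, float]]  # piece -> class -> variance
    covariances: dict[str, float] = field(default_factory=dict)  # class -> cross-cov
    priors: dict[str, float] = field(default_factory=lambda: {IDLE: 0.5, DORSIFLEX: 0.5})

    def validate(self) -> None:
        if not np.isclose(sum(self.priors.values()), 1.0):
            raise DataError("class priors must sum to 1")
        for p in CLASSES:
            for c in CLASSES:
                if self.variances[p][c] <= 0:
                    raise DataError("class-conditional variances must be positive")

    def class_gaussian(self, c: str) -> tuple[np.ndarray, np.ndarray]:
        """Mean vector and covariance matrix of (idle-piece, dorsi-piece) features."""
        mu = np.array([self.means[p][c] for p in CLASSES])
        v = [self.variances[p][c] for p in CLASSES]
        cov = float(self.covariances.get(c, 0.0))
        # keep the correlation strictly inside (-1, 1) for invertibility
        lim = 0.999 * math.sqrt(v[0] * v[1])
        cov = max(-lim, min(lim, cov))
        return mu, np.array([[v[0], cov], [cov, v[1]]])


def fit_classifier(
    feats: np.ndarray,
    labels: np.ndarray,
    priors: dict[str, float] | None = None,
) -> GaussianPieceModel:
    """Fit 1-D Gaussian class models on the per-piece features.

    ``feats`` is (trials, 2) as returned by :func:`extract_feature`.  Priors
    default to the empirical class frequencies.  A variance floor of
    1e-9 x the overall feature variance guards against degenerate densities;
    exactly zero within-class variance raises with a remediation hint.
    """
    feats = np.asarray(feats, dtype=float)
    labels = np.asarray(labels)
    if feats.ndim != 2 or feats.shape[1] != 2:
        raise DataError("feats must be (trials, 2): one column per piece")
    means: dict[str, dict[str, float]] = {}
    variances: dict[str, dict[str, float]] = {}
    for j, piece in enumerate(CLASSES):
        f = feats[:, j]
        floor = 1e-9 * max(float(np.var(f)), 1e-300)
        means[piece], variances[piece] = {}, {}
        for c in CLASSES:
            fc = f[labels == c]
            if len(fc) < 2:
                raise DataError(f"need >= 2 trials of class {c} in piece {piece}")
            v = float(np.var(fc, ddof=1))
            if v == 0.0:
                raise DataError(
                    f"zero within-class variance for class {c} in piece {piece}; "
                    "add regularization (e.g. jitter features by a small epsilon)"
                )
            means[piece][c] = float(fc.mean())
            variances[piece][c] = max(v, floor)
    covariances = {}
    for c in CLASSES:
        fc = feats[labels == c]
        covariances[c] = float(np.cov(fc[:, 0], fc[:, 1], ddof=1)[0, 1])
    if priors is None:
        priors = {c: float((labels == c).mean()) for c in CLASSES}
    model = GaussianPieceModel(
        means=means, variances=variances, covariances=covariances, priors=dict(priors)
    )
    model.validate()
    return model


def _log_gauss(f: np.ndarray, mu: float, var: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * var) + (f - mu) ** 2 / var)


def posterior(model: GaussianPieceModel, f: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior class probabilities (P_I, P_D) given per-piece features.

    Both piece features are observed at every step, so the posterior
    conditions on both: per class, the pair is scored under its bivariate
    Gaussian (with the fitted cross-covariance between the piece features)
    and combined with the prior by Bayes' rule.  ``f`` is shape (2,) or
    (n, 2); returns matching scalars/arrays with P_I + P_D = 1.
    """
    model.validate()
    f = np.asarray(f, dtype=float)
    single = f.ndim == 1
    f2 = np.atleast_2d(f)
    if f2.shape[1] != 2:
        raise DataError("per-piece feature must have 2 columns")
    lj = np.empty((f2.shape[0], 2))  # (n, class)
    for k, c in enumerate(CLASSES):
        prior = model.priors[c]
        mu, cov = model.class_gaussian(c)
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] ** 2
        inv = np.array([[cov[1, 1], -cov[0, 1]], [-cov[0, 1], cov[0, 0]]]) / det
        d = f2 - mu
        maha = inv[0, 0] * d[:, 0] ** 2 + 2 * inv[0, 1] * d[:, 0] * d[:, 1] + inv[1, 1] * d[:, 1] ** 2
        lj[:, k] = (np.log(prior) if prior > 0 else -np.inf) - 0.5 * (
            math.log(4.0 * math.pi**2 * det) + maha
        )
    mx = lj.max(axis=1, keepdims=True)
    mx = np.where(np.isfinite(mx), mx, 0.0)
    p = np.exp(lj - mx)
    p /= p.sum(axis=1, keepdims=True)
    p_i, p_d = p[:, 0], p[:, 1]
    return (float(p_i[0]), float(p_d[0])) if single else (p_i, p_d)


def classify(model: GaussianPieceModel, f: np.ndarray) -> np.ndarray:
    """Class labels from posteriors; a tie resolves to idle (no stimulation)."""
    p_i, p_d = posterior(model, np.atleast_2d(np.asarray(f, dtype=float)))
    return np.where(np.asarray(p_d) > np.asarray(p_i), DORSIFLEX, IDLE)
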