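"""Classwise-PCA feature extraction and Gaussian Bayesian classification."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from bcifes.decode import (
    GaussianPieceModel,
    classify,
    extract_feature,
    fit_classifier,
    fit_extractor,
    posterior,
)
from bcifes.exceptions import DataError
from bcifes.spectral import spectral_trials


def make_model(mu_i=-1.0, mu_d=1.0, var=1.0, priors=(0.5, 0.5), cov=0.0):
    """Hand-built two-piece model with identical pieces."""
    return GaussianPieceModel(
        means={p: {"I": mu_i, "D": mu_d} for p in "ID"},
        variances={p: {"I": var, "D": var} for p in "ID"},
        covariances={"I": cov, "D": cov},
        priors={"I": priors[0], "D": priors[1]},
    )


def embedded_gaussian_data(seed=0, n=200, dim=50, sep=4.0, eps=0.01):
    """Two 1-D Gaussians along a random axis, plus tiny off-axis noise."""
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=dim)
    axis /= np.linalg.norm(axis)
    labels = np.array(["I", "D"] * (n // 2))
    shift = np.where(labels == "D", sep / 2, -sep / 2)
    x = shift[:, None] * axis + rng.normal(size=n)[:, None] * axis
    x = x + eps * rng.normal(size=(n, dim))
    return x, labels, axis


class TestFitExtractor:
    def test_recovers_embedded_axis(self):
        x, labels, axis = embedded_gaussian_data()
        ext = fit_extractor(x, labels, variance_kept=0.99)
        for piece in "ID":
            a, _ = ext.composed_map(piece)
            angle = np.degrees(np.arccos(min(1.0, abs(a @ axis) / np.linalg.norm(a))))
            assert angle < 5.0

    def test_full_variance_keeps_class_rank(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 10))
        ext = fit_extractor(x, np.array(["I", "D"] * 15), variance_kept=1.0)
        for c in "ID":
            assert ext.bases[c].shape[1] == 10  # min(trials-1, dim) = 10

    def test_orthonormal_bases_unit_discriminants(self, small_epochs):
        st = spectral_trials(small_epochs)
        ext = fit_extractor(st.features(), st.labels)
        ext.validate()

    def test_aida_direction_close_to_lda_on_shared_covariance(self):
        # with equal class covariances the information criterion and Fisher
        # agree up to estimation error
        x, labels, _ = embedded_gaussian_data(seed=3)
        a1, _ = fit_extractor(x, labels, method="lda").composed_map("I")
        a2, _ = fit_extractor(x, labels, method="aida").composed_map("I")
        cos = abs(a1 @ a2) / (np.linalg.norm(a1) * np.linalg.norm(a2))
        assert cos > 0.95

    def test_zero_variance_data_rejected(self):
        with pytest.raises(DataError):
            fit_extractor(np.zeros((10, 5)), np.array(["I", "D"] * 5))


class TestExtractFeature:
    def test_class_center_maps_to_zero(self):
        x, labels, _ = embedded_gaussian_data(seed=2)
        ext = fit_extractor(x, labels)
        f = extract_feature(ext, ext.centers["I"])
        assert abs(f[0]) < 1e-10

    def test_linearity_of_centered_map(self):
        x, labels, _ = embedded_gaussian_data(seed=4)
        ext = fit_extractor(x, labels)
        d1, d2 = x[0], x[1]
        mu = ext.centers["I"]
        lhs = extract_feature(ext, mu + 2.0 * (d1 - mu) + 3.0 * (d2 - mu))[0]
        rhs = 2.0 * extract_feature(ext, d1)[0] + 3.0 * extract_feature(ext, d2)[0]
        assert abs(lhs - rhs) < 1e-8

    def test_matches_explicit_composed_matrix(self):
        x, labels, _ = embedded_gaussian_data(seed=5)
        ext = fit_extractor(x, labels)
        f = extract_feature(ext, x)
        for j, piece in enumerate("ID"):
            a, mu = ext.composed_map(piece)
            np.testing.assert_allclose(f[:, j], (x - mu) @ a, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        x, labels, _ = embedded_gaussian_data(seed=6)
        ext = fit_extractor(x, labels)
        with pytest.raises(DataError):
            extract_feature(ext, np.zeros(7))

    def test_training_classes_separate_on_strong_subject(self, small_epochs):
        st = spectral_trials(small_epochs)
        ext = fit_extractor(st.features(), st.labels)
        f = extract_feature(ext, st.features())
        sep = []
        for j in range(2):
            fi, fd = f[st.labels == "I", j], f[st.labels == "D", j]
            sep.append(abs(fd.mean() - fi.mean()) / np.sqrt(0.5 * (fi.var() + fd.var())))
        assert max(sep) > 2.0


class TestClassifierAndPosterior:
    def test_symmetric_classes_give_half(self):
        p_i, p_d = posterior(make_model(), np.zeros(2))
        assert abs(p_i - 0.5) < 1e-12 and abs(p_d - 0.5) < 1e-12

    def test_posteriors_sum_to_one(self):
        model = make_model(cov=0.4)
        f = np.random.default_rng(0).normal(size=(500, 2))
        p_i, p_d = posterior(model, f)
        np.testing.assert_allclose(p_i + p_d, 1.0, atol=1e-12)

    def test_strong_separation_saturates(self):
        model = make_model(mu_i=0.0, mu_d=6.0, var=1.0)
        p_i, _ = posterior(model, np.zeros(2))
        assert p_i > 0.99

    def test_degenerate_prior_wins_everywhere(self):
        model = make_model(priors=(1.0, 0.0))
        f = np.random.default_rng(1).normal(size=(50, 2))
        p_i, _ = posterior(model, f)
        np.testing.assert_allclose(p_i, 1.0)

    def test_label_swap_swaps_posteriors(self):
        rng = np.random.default_rng(2)
        feats = np.column_stack([rng.normal(0, 1, 60), rng.normal(0.5, 1, 60)])
        labels = np.array(["I", "D"] * 30)
        m1 = fit_classifier(feats, labels)
        swapped = np.where(labels == "I", "D", "I")
        m2 = fit_classifier(feats[:, ::-1], swapped)
        p1 = posterior(m1, feats)
        p2 = posterior(m2, feats[:, ::-1])
        np.testing.assert_allclose(p1[0], p2[1], atol=1e-9)
        np.testing.assert_allclose(p1[1], p2[0], atol=1e-9)

    def test_posterior_monotone_in_feature(self):
        model = make_model(mu_i=-1.0, mu_d=1.0, var=1.0)
        f = np.linspace(-4, 4, 101)
        _, p_d = posterior(model, np.column_stack([f, f]))
        assert (np.diff(p_d) >= -1e-12).all()

    def test_classification_matches_log_likelihood_ratio_oracle(self):
        # independent oracle: scipy multivariate normal log-densities
        rng = np.random.default_rng(3)
        feats = np.column_stack([rng.normal(0, 1, 200), rng.normal(1, 2, 200)])
        labels = np.array(["I", "D"] * 100)
        model = fit_classifier(feats, labels)
        test = rng.normal(0, 3, size=(1000, 2))
        pred = classify(model, test)
        llr = np.empty(1000)
        for k, c in enumerate("ID"):
            mu, cov = model.class_gaussian(c)
            lp = multivariate_normal(mu, cov).logpdf(test) + np.log(model.priors[c])
            llr = llr + lp if c == "D" else -lp
        oracle = np.where(llr > 0, "D", "I")
        np.testing.assert_array_equal(pred, oracle)

    def test_zero_within_class_variance_raises_with_hint(self):
        feats = np.column_stack([np.ones(20), np.arange(20.0)])
        with pytest.raises(DataError, match="regularization"):
            fit_classifier(feats, np.array(["I", "D"] * 10))

    def test_tie_resolves_to_idle(self):
        lab = classify(make_model(), np.zeros(2))
        assert lab[0] == "I"
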