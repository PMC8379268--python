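import numpy as np
import pytest
from scipy import linalg

from cbci.confidence import (
    SCHEMAS,
    CspModel,
    FeatureSchema,
    confidence_separation,
    extract_features,
    fit_confidence,
    fit_csp,
    reliability_slope,
)
from cbci.errors import (
    InsufficientDataError,
    MissingFeatureError,
    ParameterError,
)


def gaussian_epochs(rng, cov, n_trials, n_samples=200):
    """Trials of multichannel noise with a given spatial covariance."""
    chol = np.linalg.cholesky(cov)
    return np.einsum("cd,tds->tcs", chol, rng.standard_normal((n_trials, cov.shape[0], n_samples)))


def oracle_csp(epochs_a, epochs_b, shrinkage):
    """Independent closed-form oracle: build the documented regularized
    class covariances and solve the generalized eigenproblem directly."""
    def class_cov(ep):
        covs = []
        for x in ep:
            c = x @ x.T
            covs.append(c / np.trace(c))
        c = np.mean(covs, axis=0)
        d = c.shape[0]
        return (1 - shrinkage) * c + shrinkage * np.trace(c) / d * np.eye(d)

    ca, cb = class_cov(epochs_a), class_cov(epochs_b)
    evals, evecs = linalg.eigh(ca, ca + cb)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestFeatureSchema:
    def test_four_study_schemas(self):
        assert set(SCHEMAS) == {"rt", "rt+conf", "nf+rt", "nf+rt+conf"}
        assert SCHEMAS["nf+rt"].use_neural and not SCHEMAS["nf+rt"].use_reported_confidence
        assert SCHEMAS["nf+rt+conf"].use_reported_confidence

    def test_empty_schema_rejected(self):
        with pytest.raises(ParameterError):
            FeatureSchema(False, False, False)

    def test_names(self):
        assert SCHEMAS["nf+rt+conf"].name == "nf+rt+conf"


class TestFitCsp:
    def test_axis_aligned_two_channel(self, rng):
        """Class A varies only along axis 0, class B only along axis 1."""
        a = np.zeros((50, 2, 100))
        b = np.zeros((50, 2, 100))
        a[:, 0, :] = rng.standard_normal((50, 100))
        b[:, 1, :] = rng.standard_normal((50, 100))
        model = fit_csp(a, b, shrinkage=0.01)
        first = model.projection[:, 0] / np.abs(model.projection[:, 0]).max()
        last = model.projection[:, -1] / np.abs(model.projection[:, -1]).max()
        assert abs(first[0]) > 100 * abs(first[1])  # aligned with axis 0
        assert abs(last[1]) > 100 * abs(last[0])  # aligned with axis 1

    def test_identical_covariances_eigenvalues_half(self, rng):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        a = gaussian_epochs(rng, cov, 200)
        b = gaussian_epochs(rng, cov, 200)
        model = fit_csp(a, b, shrinkage=0.1)
        np.testing.assert_allclose(model.eigenvalues, 0.5, atol=0.05)

    @pytest.mark.parametrize("n_ch", [2, 3, 4])
    def test_matches_closed_form_oracle(self, rng, n_ch):
        base = rng.standard_normal((n_ch, n_ch))
        cov_a = base @ base.T + n_ch * np.eye(n_ch)
        cov_b = np.diag(rng.uniform(0.5, 3.0, n_ch))
        a = gaussian_epochs(rng, cov_a, 30)
        b = gaussian_epochs(rng, cov_b, 30)
        model = fit_csp(a, b, shrinkage=0.05)
        evals, evecs = oracle_csp(a, b, 0.05)
        np.testing.assert_allclose(model.eigenvalues, evals, atol=1e-8)
        for k in range(n_ch):
            v, w = model.projection[:, k], evecs[:, k]
            v = v / np.linalg.norm(v) * np.sign(v[np.argmax(np.abs(v))])
            w = w / np.linalg.norm(w) * np.sign(w[np.argmax(np.abs(w))])
            np.testing.assert_allclose(v, w, atol=1e-8)

    def test_component_variances_match_eigenvalues(self, rng):
        """On the pooled, trace-normalized training covariances the
        projected variance ratio reproduces the eigenvalues."""
        cov_a = np.array([[3.0, 0.2], [0.2, 0.5]])
        cov_b = np.array([[0.5, -0.1], [-0.1, 2.0]])
        a = gaussian_epochs(rng, cov_a, 100)
        b = gaussian_epochs(rng, cov_b, 100)
        model = fit_csp(a, b, shrinkage=0.0)

        def mean_cov(ep):
            covs = [x @ x.T / np.trace(x @ x.T) for x in ep]
            return np.mean(covs, axis=0)

        ca, cb = mean_cov(a), mean_cov(b)
        w = model.projection
        ratios = np.diag(w.T @ ca @ w) / np.diag(w.T @ (ca + cb) @ w)
        np.testing.assert_allclose(ratios, model.eigenvalues, atol=1e-10)

    def test_too_few_trials_rejected(self, rng):
        a = gaussian_epochs(rng, np.eye(2), 1)
        b = gaussian_epochs(rng, np.eye(2), 10)
        with pytest.raises(InsufficientDataError):
            fit_csp(a, b)


class TestExtractFeatures:
    def _csp(self):
        return CspModel(projection=np.eye(2), eigenvalues=np.array([0.7, 0.3]),
                        kept_components=(0, 1))

    def test_unit_variance_gives_zero_logvar(self, rng):
        x = rng.standard_normal((5, 2, 20000))
        x = (x - x.mean(-1, keepdims=True)) / x.std(-1, keepdims=True)
        feats = extract_features(SCHEMAS["nf+rt"], csp=self._csp(), epochs=x,
                                 rts=np.ones(5))
        np.testing.assert_allclose(feats[:, :2], 0.0, atol=1e-9)

    def test_rt_only_length_one(self):
        feats = extract_features(SCHEMAS["rt"], rts=np.array([0.5, 0.7]))
        assert feats.shape == (2, 1)

    def test_doubling_amplitude_adds_log4(self, rng):
        x = rng.standard_normal((3, 2, 500))
        f1 = extract_features(SCHEMAS["nf+rt"], csp=self._csp(), epochs=x, rts=np.ones(3))
        f2 = extract_features(SCHEMAS["nf+rt"], csp=self._csp(), epochs=2 * x, rts=np.ones(3))
        np.testing.assert_allclose(f2[:, :2] - f1[:, :2], np.log(4.0), atol=1e-9)

    def test_missing_input_rejected(self):
        with pytest.raises(MissingFeatureError):
            extract_features(SCHEMAS["rt+conf"], rts=np.ones(3))


class TestFitConfidence:
    def test_separable_features_high_confidence(self, rng):
        n = 400
        labels = rng.random(n) < 0.7
        rts = np.where(labels, 0.4, 1.6) + rng.normal(0, 0.01, n)
        est = fit_confidence(labels, SCHEMAS["rt"], seed=0, rts=rts)
        assert est.confidences_[labels].mean() > 0.9
        assert est.confidences_[~labels].mean() < 0.1

    def test_probability_contract(self, rng):
        n = 200
        labels = rng.random(n) < 0.75
        rts = rng.lognormal(-0.7, 0.4, n) + 0.2 * (~labels)
        est = fit_confidence(labels, SCHEMAS["rt"], seed=1, rts=rts)
        assert np.all((est.confidences_ >= 0) & (est.confidences_ <= 1))
        assert not np.any(np.isnan(est.confidences_))

    def test_shuffled_labels_no_separation(self, rng):
        """Separation on shuffled labels sits inside the refit-based
        permutation null (the honest oracle: each null draw refits the
        estimator on a fresh permutation) and is dwarfed by the
        real-label separation."""
        n = 600
        labels = rng.random(n) < 0.75
        rts = rng.lognormal(-0.7, 0.4, n) + 0.35 * (~labels)
        draws = []
        for rep in range(6):
            shuffled = rng.permutation(labels)
            est = fit_confidence(shuffled, SCHEMAS["rt"], seed=2 + rep, rts=rts)
            draws.append(confidence_separation(est.confidences_, shuffled)[2])
        # null separations hover near zero (CV fold-coupling widens them
        # slightly beyond the naive fixed-confidence permutation CI)
        assert np.max(np.abs(draws)) < 0.05
        real = fit_confidence(labels, SCHEMAS["rt"], seed=2, rts=rts)
        real_sep = confidence_separation(real.confidences_, labels)[2]
        assert real_sep > 0.1  # an order of magnitude above the null draws

    def test_out_of_fold_partition(self, rng):
        n = 160
        labels = rng.random(n) < 0.7
        rts = rng.lognormal(-0.7, 0.4, n)
        est = fit_confidence(labels, SCHEMAS["rt"], seed=3, rts=rts)
        assert set(est.fold_assignment) == set(range(8))
        # stratification keeps the class ratio in every fold
        for k in range(8):
            fold_labels = labels[est.fold_assignment == k]
            assert 0 < fold_labels.mean() < 1

    def test_determinism(self, rng):
        n = 120
        labels = rng.random(n) < 0.7
        rts = rng.lognormal(-0.7, 0.4, n)
        a = fit_confidence(labels, SCHEMAS["rt"], seed=9, rts=rts)
        b = fit_confidence(labels, SCHEMAS["rt"], seed=9, rts=rts)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_array_equal(a.confidences_, b.confidences_)

    def test_single_class_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_confidence(np.ones(50, dtype=bool), SCHEMAS["rt"], rts=np.ones(50))

    def test_too_few_trials_rejected(self, rng):
        labels = np.array([True, False, True, False])
        with pytest.raises(InsufficientDataError):
            fit_confidence(labels, SCHEMAS["rt"], rts=np.ones(4))

    def test_neural_schema_uses_csp_per_fold(self, rng):
        n = 96
        labels = rng.random(n) < 0.6
        epochs = rng.standard_normal((n, 3, 48))
        epochs[labels, 0, :] *= 3.0  # class-dependent variance
        rts = rng.lognormal(-0.7, 0.3, n)
        est = fit_confidence(labels, SCHEMAS["nf+rt"], seed=4, epochs=epochs,
                             rts=rts, shrinkage=0.1, min_samples_leaf=5)
        assert len(est.csp_per_fold) == 8
        assert all(c is not None for c in est.csp_per_fold)
        _, _, diff = confidence_separation(est.confidences_, labels)
        assert diff > 0.1  # variance signal is decodable


class TestConfidenceSeparation:
    def test_constant_confidence_zero_difference(self):
        labels = np.array([True, False, True])
        mc, mi, d = confidence_separation(np.full(3, 0.7), labels)
        assert (mc, mi, d) == (0.7, 0.7, 0.0)

    def test_perfect_separation(self):
        labels = np.array([True, True, False])
        mc, mi, d = confidence_separation(np.array([1.0, 1.0, 0.0]), labels)
        assert d == 1.0

    def test_single_class_nan_difference(self):
        labels = np.ones(3, dtype=bool)
        _, mi, d = confidence_separation(np.full(3, 0.5), labels)
        assert np.isnan(mi) and np.isnan(d)


class TestReliabilitySlope:
    def test_perfectly_calibrated_synthetic(self, rng):
        conf = rng.uniform(0.1, 0.9, 20000)
        labels = rng.random(20000) < conf
        assert reliability_slope(conf, labels) == pytest.approx(1.0, abs=0.1)
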