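"""Unit tests for the GP core: kernel, evidence, fitting, prediction."""

import numpy as np
import pytest
from scipy import linalg

from gpnorm.gp import (
    CovariateMatrix,
    FitConfig,
    GPHyperparams,
    TrainedGP,
    fit_gp,
    gp_predict,
    log_marginal_likelihood,
    se_ard_kernel,
)


def _dense_lml(hyper, X, y):
    """Brute-force evidence: explicit inverse and log-determinant."""
    n = len(y)
    C = se_ard_kernel(X, X, hyper) + hyper.noise_variance * np.eye(n)
    C = C + 1e-8 * hyper.amplitude * np.eye(n)  # same jitter as the implementation
    return (
        -0.5 * y @ np.linalg.inv(C) @ y
        - 0.5 * np.linalg.slogdet(C)[1]
        - 0.5 * n * np.log(2 * np.pi)
    )


class TestKernel:
    @pytest.mark.parametrize(
        "a,ls,xp,xq,expected",
        [
            (3.0, [2.0], [[1.5]], [[1.5]], 3.0),  # zero distance -> amplitude
            (1.0, [1.0], [[0.0]], [[np.sqrt(2)]], np.exp(-1.0)),
            (2.0, [1.0, 2.0], [[0.0, 0.0]], [[1.0, 2.0]], 2.0 * np.exp(-1.0)),
        ],
    )
    def test_hand_values(self, a, ls, xp, xq, expected):
        h = GPHyperparams(a, ls, 1.0)
        assert se_ard_kernel(xp, xq, h) == pytest.approx(expected, rel=1e-12)

    def test_symmetric_psd_and_bounded(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 3))
        h = GPHyperparams(1.7, [0.5, 1.0, 2.0], 0.1)
        K = se_ard_kernel(X, X, h)
        assert np.allclose(K, K.T)
        assert np.min(np.linalg.eigvalsh(K)) > -1e-10
        assert np.all((K > 0) & (K <= h.amplitude + 1e-12))

    def test_dimension_mismatch_rejected(self):
        h = GPHyperparams(1.0, [1.0, 1.0], 0.1)
        with pytest.raises(ValueError):
            se_ard_kernel([[0.0]], [[0.0]], h)
        with pytest.raises(ValueError):
            se_ard_kernel([[0.0, 0.0]], [[0.0, 0.0, 0.0]], h)

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            GPHyperparams(-1.0, [1.0], 0.1)
        with pytest.raises(ValueError):
            GPHyperparams(1.0, [0.0], 0.1)


class TestEvidence:
    def test_single_point_tiny_amplitude_is_standard_normal_density(self):
        h = GPHyperparams(1e-12, [1.0], 1.0)
        lml = log_marginal_likelihood(h, [[0.0]], [0.0], return_grad=False)
        assert lml == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-9)

    def test_two_distant_points_become_iid(self):
        h = GPHyperparams(1.0, [1.0], 1.0)
        lml = log_marginal_likelihood(h, [[0.0], [1e6]], [0.0, 0.0], return_grad=False)
        # absolute tolerance accommodates the 1e-8 diagonal jitter
        assert lml == pytest.approx(-np.log(4 * np.pi), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 9)
        m = rng.integers(1, 4)
        X = rng.normal(size=(n, m))
        y = rng.normal(size=n)
        h = GPHyperparams(
            float(rng.uniform(0.5, 2)), rng.uniform(0.5, 2, size=m), float(rng.uniform(0.1, 1))
        )
        lml = log_marginal_likelihood(h, X, y, return_grad=False)
        assert lml == pytest.approx(_dense_lml(h, X, y), rel=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_gradient_matches_central_differences(self, seed):
        rng = np.random.default_rng(seed + 50)
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        h = GPHyperparams(float(rng.uniform(0.5, 2)), rng.uniform(0.5, 2, size=2), 0.3)
        _, grad = log_marginal_likelihood(h, X, y)
        v0 = h.to_log_vector()
        for i in range(v0.size):
            e = np.zeros_like(v0)
            e[i] = 1e-5
            num = (
                log_marginal_likelihood(GPHyperparams.from_log_vector(v0 + e), X, y, False)
                - log_marginal_likelihood(GPHyperparams.from_log_vector(v0 - e), X, y, False)
            ) / 2e-5
            assert grad[i] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestFit:
    def test_recovers_known_hyperparameters(self):
        """Median log-hyperparameter error over 20 replicates within 0.5."""
        errs = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            X = rng.uniform(-2, 2, size=(200, 1))
            h = GPHyperparams(1.0, [0.5], 0.01)
            K = se_ard_kernel(X, X, h) + 0.01 * np.eye(200)
            y = np.linalg.cholesky(K + 1e-10 * np.eye(200)) @ rng.standard_normal(200)
            m = fit_gp(X, y, FitConfig(n_restarts=2), seed=s)
            ls_true = 0.5 / X.std()  # truth in standardized-covariate units
            errs.append(
                [
                    np.log(m.hyper.amplitude) - np.log(1.0),
                    np.log(m.hyper.length_scales[0]) - np.log(ls_true),
                    np.log(m.hyper.noise_variance) - np.log(0.01),
                ]
            )
        med = np.median(np.abs(errs), axis=0)
        assert np.all(med < 0.5)

    def test_constant_targets_finite_evidence_tiny_variance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        m = fit_gp(X, np.full(20, 3.7), FitConfig(n_restarts=1), seed=0)
        assert np.isfinite(m.log_evidence)
        assert m.hyper.amplitude + m.hyper.noise_variance < 1e-6

    def test_ard_downweights_irrelevant_covariate(self):
        """Irrelevant column gets the longer fitted length scale (median of 20)."""
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            t = rng.uniform(-2, 2, size=100)
            junk = rng.normal(size=100)
            y = np.sin(1.5 * t) + 0.05 * rng.standard_normal(100)
            m = fit_gp(np.column_stack([t, junk]), y, FitConfig(n_restarts=2), seed=s)
            wins += m.hyper.length_scales[1] > m.hyper.length_scales[0]
        assert wins > 10

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        m1 = fit_gp(X, y, seed=7)
        m2 = fit_gp(X, y, seed=7)
        assert m1.hyper.to_log_vector() == pytest.approx(m2.hyper.to_log_vector(), abs=0)

    def test_evidence_not_below_initialization(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.standard_normal(40)
        m = fit_gp(X, y, seed=0)
        Xc = CovariateMatrix(X.copy()).fit_standardization()
        yc = y - y.mean()
        var_y = yc.var()
        h0 = GPHyperparams(var_y, np.ones(2), var_y / 2)
        lml0 = log_marginal_likelihood(h0, Xc.standardized(), yc, return_grad=False)
        assert m.log_evidence >= lml0 - 1e-9

    def test_cached_factorization_reconstructs_covariance(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(25, 2))
        y = rng.normal(size=25)
        m = fit_gp(X, y, FitConfig(n_restarts=1), seed=0)
        Xs = m.train_covariates.standardized()
        C = se_ard_kernel(Xs, Xs, m.hyper) + m.hyper.noise_variance * np.eye(25)
        rec = m.chol_factor @ m.chol_factor.T
        assert np.max(np.abs(rec - C)) / np.max(np.abs(C)) < 1e-7


class TestPredict:
    def _manual_model(self, hyper, X, y):
        Xc = CovariateMatrix(np.atleast_2d(X))
        Xc.shift = np.zeros(Xc.m)
        Xc.scale = np.ones(Xc.m)
        Xs = Xc.standardized()
        C = se_ard_kernel(Xs, Xs, hyper) + hyper.noise_variance * np.eye(len(y))
        L = np.linalg.cholesky(C)
        return TrainedGP(
            hyper, Xc, np.asarray(y, float), L,
            linalg.cho_solve((L, True), np.asarray(y, float)), 0.0,
        )

    def test_single_point_hand_values(self):
        m = self._manual_model(GPHyperparams(1.0, [1.0], 1.0), [[0.0]], [2.0])
        r = gp_predict(m, [[0.0]], ystar=[2.0])
        assert r.mean[0] == pytest.approx(1.0)
        assert r.observation_variance[0] == pytest.approx(1.5)
        assert r.z[0] == pytest.approx(1.0 / np.sqrt(1.5))

    def test_noise_free_interpolation(self):
        m = self._manual_model(GPHyperparams(1.0, [1.0], 1e-10), [[0.0], [1.0]], [0.3, -0.2])
        r = gp_predict(m, [[0.0], [1.0]])
        assert r.mean == pytest.approx([0.3, -0.2], abs=1e-6)
        assert np.all(r.latent_variance < 1e-6)

    def test_prior_reasserts_far_from_data(self):
        m = self._manual_model(GPHyperparams(1.3, [1.0], 0.2), [[0.0]], [5.0])
        r = gp_predict(m, [[1e5]])
        assert r.mean[0] == pytest.approx(0.0, abs=1e-10)
        assert r.observation_variance[0] == pytest.approx(1.3 + 0.2, rel=1e-9)

    def test_variance_ordering_invariants(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        m = fit_gp(X, y, FitConfig(n_restarts=1), seed=0)
        r = gp_predict(m, rng.normal(size=(15, 2)), ystar=rng.normal(size=15))
        assert np.all(r.observation_variance >= m.hyper.noise_variance - 1e-12)
        assert np.all(r.observation_variance >= r.latent_variance)
        assert np.all(np.isfinite(r.z))

    def test_added_training_point_never_increases_latent_variance(self):
        rng = np.random.default_rng(7)
        h = GPHyperparams(1.0, [1.0], 0.3)
        X = rng.normal(size=(10, 1))
        y = rng.normal(size=10)
        Xstar = rng.normal(size=(20, 1))
        base = gp_predict(self._manual_model(h, X, y), Xstar).latent_variance
        Xp = np.vstack([X, rng.normal(size=(1, 1))])
        yp = np.append(y, rng.normal())
        more = gp_predict(self._manual_model(h, Xp, yp), Xstar).latent_variance
        assert np.all(more <= base + 1e-10)

    def test_serialization_round_trip(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        m = fit_gp(X, y, FitConfig(n_restarts=1), seed=0)
        m2 = TrainedGP.from_json(m.to_json())
        assert m2.hyper.to_log_vector() == pytest.approx(m.hyper.to_log_vector(), abs=1e-12)
        Xstar = rng.normal(size=(5, 3))
        r1, r2 = gp_predict(m, Xstar), gp_predict(m2, Xstar)
        assert r2.mean == pytest.approx(r1.mean, abs=1e-10)
        assert r2.observation_variance == pytest.approx(r1.observation_variance, abs=1e-10)

    def test_test_rows_standardized_with_training_statistics(self):
        rng = np.random.default_rng(9)
        X = rng.normal(10.0, 2.0, size=(30, 1))
        y = np.sin(X[:, 0])
        m = fit_gp(X, y, FitConfig(n_restarts=1), seed=0)
        # a test row equal to a training row must map onto it exactly,
        # regardless of the test batch's own spread
        r_alone = gp_predict(m, X[:1])
        r_batch = gp_predict(m, np.vstack([X[:1], [[1000.0]]]))
        assert r_batch.mean[0] == pytest.approx(r_alone.mean[0], rel=1e-12)
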