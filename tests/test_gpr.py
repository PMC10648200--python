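"""GP regression: kernel, profiled likelihood, fitting, posterior."""

import math

import numpy as np
import pytest
from scipy.linalg import cho_solve, cholesky

from solegrf.gpr import (GPRConfig, GPRHyperparams, GPRModel, _fit_arrays,
                         _nll_and_grad, beta_hat, log_marginal_likelihood,
                         predict_gpr, se_kernel, se_kernel_matrix)
from solegrf.synthetic import DomainError


def make_model(X, y, sigma_f, sigma_l, sigma2, include_noise=True):
    """Hand-built posterior with fixed hyperparameters (no optimization)."""
    n = y.size
    A = se_kernel_matrix(X, X, sigma_f, sigma_l) + sigma2 * np.eye(n)
    L = cholesky(A, lower=True)
    ones = np.ones(n)
    Ai1 = cho_solve((L, True), ones)
    Aiy = cho_solve((L, True), y)
    beta = float(ones @ Aiy) / float(ones @ Ai1)
    hp = GPRHyperparams(math.log(sigma_f), math.log(sigma_l), sigma2, beta)
    return GPRModel(X_train=X, y_train=y, feat_mean=np.zeros(X.shape[1]),
                    feat_std=np.ones(X.shape[1]), y_mean=0.0, hyperparams=hp,
                    chol_lower=L, alpha=Aiy - beta * Ai1, jitter=0.0,
                    lml=0.0, lml_init=0.0,
                    config=GPRConfig(include_noise_in_interval=include_noise))


class TestKernel:
    def test_equal_inputs_give_signal_variance(self, rng):
        f = rng.normal(size=12)
        assert se_kernel(f, f, 1.7, 0.9) == pytest.approx(1.7 ** 2)

    def test_characteristic_distance_value(self):
        sl = 0.8
        fi = np.zeros(12)
        fj = np.zeros(12)
        fj[0] = sl * math.sqrt(2.0)
        assert se_kernel(fi, fj, 2.0, sl) == pytest.approx(4.0 * math.exp(-1.0))

    def test_monotone_decay_to_zero(self):
        vals = [se_kernel(np.zeros(3), np.array([d, 0, 0]), 1.0, 1.0)
                for d in np.linspace(0, 8, 40)]
        assert all(a > b > 0 for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-12

    def test_matrix_symmetry(self, rng):
        X = rng.normal(size=(15, 4))
        K = se_kernel_matrix(X, X, 1.3, 0.7)
        assert np.allclose(K, K.T)
        assert np.allclose(np.diag(K), 1.3 ** 2)

    def test_invalid_hyperparameters(self):
        with pytest.raises(DomainError):
            se_kernel(np.zeros(3), np.ones(3), -1.0, 1.0)


class TestBetaHat:
    def test_identity_covariance_reduces_to_mean(self, rng):
        F = rng.normal(size=30)
        b = beta_hat(np.eye(30), np.ones((30, 1)), F)
        assert b.item() == pytest.approx(F.mean(), abs=1e-10)

    def test_constant_response_recovered_for_any_spd(self, rng):
        A = rng.normal(size=(20, 20))
        K = A @ A.T + 20 * np.eye(20)
        b = beta_hat(K, np.ones((20, 1)), np.full(20, 4.2))
        assert b.item() == pytest.approx(4.2, abs=1e-8)

    def test_two_by_two_hand_case(self):
        b = beta_hat(np.array([[2.0, 0.0], [0.0, 2.0]]), np.ones((2, 1)),
                     np.array([4.0, 8.0]))
        assert b.item() == pytest.approx(6.0, abs=1e-12)


class TestLogMarginalLikelihood:
    def test_single_point_closed_form(self):
        # quadratic term vanishes when F = Hβ̂ (β̂ = F for n=1)
        v = 0.7
        got = log_marginal_likelihood((0.5 * math.log(v - 0.2), 0.0), 0.2,
                                      np.zeros((1, 1)), np.array([3.0]))
        assert got == pytest.approx(-0.5 * math.log(2 * math.pi)
                                    - 0.5 * math.log(v), abs=1e-10)

    def test_matches_dense_oracle(self, rng):
        for _ in range(5):
            X = rng.normal(size=(20, 4))
            y = rng.normal(size=20)
            sf, sl, s2 = 1.2, 1.5, 0.3
            K = se_kernel_matrix(X, X, sf, sl) + s2 * np.eye(20)
            Ki = np.linalg.inv(K)
            H = np.ones((20, 1))
            beta = np.linalg.solve(H.T @ Ki @ H, H.T @ Ki @ y).item()
            r = y - beta
            expected = (-0.5 * r @ Ki @ r - 10 * math.log(2 * math.pi)
                        - 0.5 * np.linalg.slogdet(K)[1])
            got = log_marginal_likelihood((math.log(sf), math.log(sl)), s2, X, y)
            assert got == pytest.approx(expected, abs=1e-8)

    def test_noise_profile_is_unimodal_near_truth(self, rng):
        """On pure iid noise the likelihood peaks where σ² meets the noise
        variance (σf absorbs nothing), rising before and falling after."""
        y = rng.normal(size=50) * 0.5  # noise variance 0.25
        X = rng.normal(size=(50, 3)) * 10.0  # far-apart inputs: K ≈ diagonal
        lml = [log_marginal_likelihood((math.log(1e-3), 0.0), s2, X, y)
               for s2 in (0.05, 0.25, 1.0)]
        assert lml[1] > lml[0] and lml[1] > lml[2]

    def test_gradient_matches_finite_differences(self, rng):
        from scipy.spatial.distance import cdist
        X = rng.normal(size=(25, 4))
        y = rng.normal(size=25)
        D2 = cdist(X, X, "sqeuclidean")
        p0 = np.array([0.1, -0.2, 0.3])
        _, grad = _nll_and_grad(p0, D2, y)
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1e-6
            fp, _ = _nll_and_grad(p0 + e, D2, y)
            fm, _ = _nll_and_grad(p0 - e, D2, y)
            assert grad[i] == pytest.approx((fp - fm) / 2e-6, rel=1e-4)


class TestPredict:
    def test_matches_dense_oracle(self, rng):
        n, m = 40, 9
        X = rng.normal(size=(n, 12))
        y = rng.normal(size=n)
        Xt = rng.normal(size=(m, 12))
        sf, sl, s2 = 1.3, 2.2, 0.05
        model = make_model(X, y, sf, sl, s2)
        dist = predict_gpr(model, Xt, full_cov=True)
        K = se_kernel_matrix(X, X, sf, sl) + s2 * np.eye(n)
        Ki = np.linalg.inv(K)
        H = np.ones((n, 1))
        beta = np.linalg.solve(H.T @ Ki @ H, H.T @ Ki @ y).item()
        ks = se_kernel_matrix(Xt, X, sf, sl)
        mu = beta + ks @ Ki @ (y - beta)
        Sigma = se_kernel_matrix(Xt, Xt, sf, sl) - ks @ Ki @ ks.T
        assert np.allclose(dist.mean, mu, atol=1e-8)
        assert np.allclose(dist.cov, Sigma, atol=1e-8)
        assert np.allclose(dist.variance, np.diag(Sigma) + s2, atol=1e-8)

    def test_noise_free_interpolation(self, rng):
        X = rng.normal(size=(30, 5))
        y = np.sin(X[:, 0]) + np.cos(X[:, 1])
        model = make_model(X, y, 1.0, 2.0, 1e-10)
        dist = predict_gpr(model, X)
        assert np.allclose(dist.mean, y, atol=1e-6)

    def test_far_field_reverts_to_basis_and_prior_variance(self, rng):
        X = rng.normal(size=(25, 3))
        y = rng.normal(size=25) + 2.0
        sf, s2 = 1.4, 0.02
        model = make_model(X, y, sf, 1.0, s2)
        far = np.full((4, 3), 1e3)
        dist = predict_gpr(model, far)
        assert np.allclose(dist.mean, model.hyperparams.beta, atol=1e-9)
        assert np.allclose(dist.variance, sf ** 2 + s2, atol=1e-9)

    def test_ci_is_mean_plus_minus_196_sd(self, rng):
        model = make_model(rng.normal(size=(20, 3)), rng.normal(size=20),
                           1.0, 1.0, 0.1)
        dist = predict_gpr(model, rng.normal(size=(6, 3)))
        assert np.allclose(dist.ci95_high - dist.mean,
                           1.96 * np.sqrt(dist.variance))
        assert np.allclose(dist.mean - dist.ci95_low,
                           1.96 * np.sqrt(dist.variance))

    def test_posterior_variance_bounded_by_prior(self, rng):
        model = make_model(rng.normal(size=(50, 4)), rng.normal(size=50),
                           2.0, 1.5, 0.01)
        dist = predict_gpr(model, rng.normal(size=(40, 4)), full_cov=True)
        assert np.all(np.diag(dist.cov) <= 2.0 ** 2 + 1e-8)
        eig = np.linalg.eigvalsh((dist.cov + dist.cov.T) / 2)
        assert eig.min() > -1e-8 * eig.max()
        assert np.all(dist.variance > 0)

    def test_duplicated_training_set_equals_halved_noise(self, rng):
        """Duplicating every observation is algebraically equivalent to a
        single copy with half the noise variance."""
        X = rng.normal(size=(25, 3))
        y = np.sin(X).sum(axis=1) + 0.1 * rng.normal(size=25)
        Xt = rng.normal(size=(8, 3))
        m_dup = make_model(np.vstack([X, X]), np.concatenate([y, y]),
                           1.0, 1.5, 0.2)
        m_half = make_model(X, y, 1.0, 1.5, 0.1)
        p_dup = predict_gpr(m_dup, Xt)
        p_half = predict_gpr(m_half, Xt)
        rel = (np.sqrt(np.mean((p_dup.mean - p_half.mean) ** 2))
               / np.sqrt(np.mean(p_half.mean ** 2)))
        assert rel < 1e-6


class TestFit:
    def test_likelihood_never_below_initialization(self, rng):
        for _ in range(3):
            X = rng.normal(size=(60, 5))
            y = np.sin(X[:, 0]) + 0.2 * rng.normal(size=60)
            model = _fit_arrays(X, y, GPRConfig(seed=0))
            assert model.lml >= model.lml_init - 1e-9

    def test_zero_response_gives_zero_posterior(self, rng):
        X = rng.normal(size=(30, 4))
        model = _fit_arrays(X, np.zeros(30), GPRConfig(seed=0))
        assert abs(model.hyperparams.beta) < 1e-8
        dist = predict_gpr(model, rng.normal(size=(5, 4)))
        assert np.allclose(dist.mean, 0.0, atol=1e-6)

    def test_too_few_rows(self, rng):
        with pytest.raises(DomainError):
            _fit_arrays(rng.normal(size=(5, 3)), np.ones(5), GPRConfig())

    def test_factorization_consistency(self, rng):
        """L·Lᵀ reproduces K+σ²I and α solves the linear system."""
        X = rng.normal(size=(50, 4))
        y = np.cos(X[:, 0]) + 0.1 * rng.normal(size=50)
        model = _fit_arrays(X, y, GPRConfig(seed=0))
        hp = model.hyperparams
        A = (se_kernel_matrix(model.X_train, model.X_train, hp.sigma_f,
                              hp.sigma_l)
             + (hp.sigma2 + model.jitter) * np.eye(model.n))
        L = model.chol_lower
        assert np.linalg.norm(L @ L.T - A) / np.linalg.norm(A) < 1e-8
        r = model.y_train - hp.beta
        resid = np.linalg.norm(A @ model.alpha - r) / max(np.linalg.norm(r), 1e-12)
        assert resid < 1e-6

    def test_save_load_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(30, 4))
        y = np.sin(X[:, 0])
        model = _fit_arrays(X, y, GPRConfig(seed=0))
        model.save(tmp_path / "gp")
        clone = GPRModel.load(tmp_path / "gp")
        Xt = rng.normal(size=(6, 4))
        assert np.allclose(predict_gpr(model, Xt).mean,
                           predict_gpr(clone, Xt).mean)


class TestAgainstReferenceImplementation:
    def test_matches_sklearn_on_random_problems(self, rng):
        """Independent cross-check: with identical fixed hyperparameters our
        posterior agrees with scikit-learn's GP (constant-mean handled by
        subtracting β̂)."""
        sklearn = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        for _ in range(10):
            n, m = 30, 6
            X = rng.normal(size=(n, 4))
            y = rng.normal(size=n)
            Xt = rng.normal(size=(m, 4))
            sf, sl, s2 = 1.5, 1.2, 0.1
            model = make_model(X, y, sf, sl, s2)
            beta = model.hyperparams.beta
            gp = GaussianProcessRegressor(
                kernel=ConstantKernel(sf ** 2, "fixed") * RBF(sl, "fixed"),
                alpha=s2, optimizer=None)
            gp.fit(X, y - beta)
            mu_ref, sd_ref = gp.predict(Xt, return_std=True)
            dist = predict_gpr(model, Xt)
            assert np.allclose(dist.mean, mu_ref + beta, atol=1e-6)
            assert np.allclose(np.sqrt(dist.variance - s2), sd_ref, atol=1e-6)
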