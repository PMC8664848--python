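"""Multi-task GP checks against independent dense-Gaussian oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from psqi_geo import _mll
from psqi_geo.kernels import (
    MeanPolyCoeffs,
    SMKernelParams,
    quadratic_mean,
    sm_kernel_matrix,
    task_covariance,
)
from psqi_geo.mtgpr import MultiTaskGPRegressor, neg_log_marginal_likelihood


def _random_setup(seed, N=12, M=3, Q=2, r=2):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (N, 2))
    Z = rng.normal(0, 1, (N, M))
    kernel = SMKernelParams(
        weights=rng.uniform(0.2, 1.5, Q),
        means=rng.uniform(0.0, 2.0, (Q, 2)),
        variances=rng.uniform(0.05, 1.0, (Q, 2)),
    )
    B = rng.normal(0, 0.7, (M, r))
    vtask = rng.uniform(0.1, 0.6, M)
    noise = rng.uniform(0.05, 0.3, M)
    C = MeanPolyCoeffs(rng.normal(0, 0.3, (6, M)))
    return X, Z, kernel, B, vtask, noise, C


def _dense_sigma(X, kernel, B, vtask, noise):
    Kx = sm_kernel_matrix(X, X, kernel)
    Kf = task_covariance(B, vtask)
    return np.kron(Kf, Kx) + np.kron(np.diag(noise), np.eye(X.shape[0])), Kf, Kx


class TestLikelihood:
    def test_single_point_closed_form(self):
        """One point, one task, unit total variance: NLL = ½ log 2π."""
        kernel = SMKernelParams(np.array([0.5]), np.zeros((1, 2)), np.ones((1, 2)))
        C = np.zeros((6, 1))
        C[0, 0] = 2.0
        val = neg_log_marginal_likelihood(
            X=np.array([[0.3, 0.7]]),
            Z=np.array([[2.0]]),  # equals the mean → zero residual
            kernel=kernel,
            B=np.array([[0.0]]),
            vtask=np.array([1.0]),  # 0.5·1 + 0.5 = 1 total variance
            noise=np.array([0.5]),
            mean_coeffs=MeanPolyCoeffs(C),
        )
        assert abs(val - 0.5 * np.log(2 * np.pi)) < 1e-10

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_multivariate_logpdf(self, seed):
        X, Z, kernel, B, vtask, noise, C = _random_setup(seed)
        sigma, _, _ = _dense_sigma(X, kernel, B, vtask, noise)
        res = (Z - quadratic_mean(X, C)).T.reshape(-1)
        oracle = -multivariate_normal.logpdf(res, mean=np.zeros(res.size), cov=sigma)
        ours = neg_log_marginal_likelihood(X, Z, kernel, B, vtask, noise, C)
        assert abs(ours - oracle) < 1e-8 * max(1.0, abs(oracle))

    @pytest.mark.parametrize("seed", [3, 4])
    def test_analytic_gradient_matches_finite_differences(self, seed):
        X, Z, *_ = _random_setup(seed, N=10, M=3)
        packing = _mll.Packing(Q=2, M=3, r=2)
        box = (0.1, 100.0)
        rng = np.random.default_rng(seed + 100)
        theta = rng.normal(0, 0.5, packing.size)
        _, grad = _mll.nll_grad(theta, X, Z, packing, box)
        h = 1e-5
        for j in range(packing.size):
            e = np.zeros(packing.size)
            e[j] = h
            fd = (
                _mll.nll(theta + e, X, Z, packing, box)
                - _mll.nll(theta - e, X, Z, packing, box)
            ) / (2 * h)
            assert abs(grad[j] - fd) < 1e-4 * max(1.0, abs(fd))


class TestPrediction:
    def _fitted(self, seed=0):
        X, Z, kernel, B, vtask, noise, C = _random_setup(seed, N=25, M=3)
        return MultiTaskGPRegressor.from_parameters(X, Z, kernel, B, vtask, noise, C)

    def test_kron_and_dense_agree(self):
        model = self._fitted()
        Xs = np.random.default_rng(1).uniform(0, 1, (15, 2))
        m1, c1 = model.predict(Xs, return_cov=True, method="kron")
        m2, c2 = model.predict(Xs, return_cov=True, method="dense")
        assert np.max(np.abs(m1 - m2)) < 1e-8
        assert np.max(np.abs(c1 - c2)) < 1e-8

    def test_matches_joint_gaussian_conditioning_oracle(self):
        """Condition the full (train ∪ test) Gaussian directly with numpy."""
        X, Z, kernel, B, vtask, noise, C = _random_setup(7, N=15, M=3)
        model = MultiTaskGPRegressor.from_parameters(X, Z, kernel, B, vtask, noise, C)
        xs = np.array([[0.35, 0.65]])
        sigma, Kf, _ = _dense_sigma(X, kernel, B, vtask, noise)
        kstar = sm_kernel_matrix(X, xs, kernel)[:, 0]
        H = np.kron(Kf, kstar[:, None])  # task-major cross covariance
        kxx = float(kernel.weights.sum())
        res = (Z - quadratic_mean(X, C)).T.reshape(-1)
        Sinv = np.linalg.inv(sigma)
        mu = quadratic_mean(xs, C)[0] + H.T @ Sinv @ res
        cov = kxx * Kf - H.T @ Sinv @ H
        m, c = model.predict(xs, return_cov=True)
        assert np.max(np.abs(m[0] - mu)) < 1e-8
        assert np.max(np.abs(c[0] - cov)) < 1e-8

    def test_single_task_reduces_to_standard_gp(self):
        """M = 1 collapses to the textbook GP conditional with k' = Kf·k."""
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, (20, 2))
        y = np.sin(4 * X[:, 0]) + 0.1 * rng.normal(size=20)
        kernel = SMKernelParams(np.array([1.0]), np.zeros((1, 2)), np.full((1, 2), 0.4))
        B = np.array([[0.8]])
        vtask = np.array([0.3])
        noise = np.array([0.05])
        C = MeanPolyCoeffs(np.zeros((6, 1)))
        model = MultiTaskGPRegressor.from_parameters(X, y, kernel, B, vtask, noise, C)
        xs = rng.uniform(0, 1, (8, 2))
        kf = 0.8**2 + 0.3
        K = kf * sm_kernel_matrix(X, X, kernel) + noise[0] * np.eye(20)
        ks = kf * sm_kernel_matrix(X, xs, kernel)
        sol = np.linalg.solve(K, y)
        mu = ks.T @ sol
        var = kf * kernel.weights.sum() - np.einsum("ib,ib->b", ks, np.linalg.solve(K, ks))
        m, c = model.predict(xs, return_cov=True)
        assert np.max(np.abs(m[:, 0] - mu)) < 1e-8
        assert np.max(np.abs(c[:, 0, 0] - var)) < 1e-8

    def test_interpolates_training_data_as_noise_vanishes(self):
        X, Z, kernel, B, vtask, _, C = _random_setup(5, N=15, M=3)
        model = MultiTaskGPRegressor.from_parameters(
            X, Z, kernel, B, vtask, np.full(3, 1e-10), C
        )
        m, c = model.predict(X, return_cov=True)
        assert np.max(np.abs(m - Z)) < 1e-3
        assert np.max(np.abs(c)) < 1e-3

    def test_predictive_variance_never_exceeds_prior(self):
        model = self._fitted(2)
        Xs = np.random.default_rng(2).uniform(-0.5, 1.5, (50, 2))
        _, covs = model.predict(Xs, return_cov=True)
        prior = float(model.kernel_params_.weights.sum()) * np.diag(model.Kf_)
        assert np.all(np.diagonal(covs, axis1=1, axis2=2) <= prior[None, :] + 1e-8)
        # far from data, the variance approaches the prior
        far = model.predict(np.array([[50.0, 50.0]]), return_cov=True)[1][0]
        assert np.max(np.abs(np.diag(far) - prior)) < 1e-6

    def test_batching_does_not_change_results(self):
        model = self._fitted(3)
        Xs = np.random.default_rng(3).uniform(0, 1, (37, 2))
        m_full, c_full = model.predict(Xs, return_cov=True, batch_size=None)
        for bs in (1, 5, 64):
            m, c = model.predict(Xs, return_cov=True, batch_size=bs)
            assert np.max(np.abs(m - m_full)) < 1e-10
            assert np.max(np.abs(c - c_full)) < 1e-10


@pytest.fixture(scope="module")
def toy_fit():
    rng = np.random.default_rng(21)
    X = rng.uniform(0, 1, (40, 2))
    f = np.sin(3 * X @ np.array([1.0, 0.7]))
    Z = np.column_stack([f + 0.05 * rng.normal(size=40),
                         0.8 * f + 0.05 * rng.normal(size=40)])
    est = MultiTaskGPRegressor(Q=1, rank=1, n_iter=120, random_state=0)
    return X, Z, est.fit(X, Z)


class TestFitting:
    def test_training_reduces_negative_log_likelihood(self, toy_fit):
        _, _, model = toy_fit
        assert model.nll_ < model.trace_[0]

    def test_fit_explains_correlated_tasks(self, toy_fit):
        X, Z, model = toy_fit
        pred = model.predict(X)
        r2 = 1 - ((pred - Z) ** 2).mean(0) / Z.var(0)
        assert np.all(r2 > 0.8)
        assert model.task_correlation_[0, 1] > 0.8

    def test_lengthscales_respect_box(self, toy_fit):
        _, _, model = toy_fit
        ell = 1.0 / (2 * np.pi * np.sqrt(model.kernel_params_.variances))
        lo, hi = model.kernel_params_.lengthscale_box
        assert np.all(ell > lo) and np.all(ell < hi)

    def test_same_seed_is_bit_for_bit_reproducible(self, toy_fit):
        X, Z, model = toy_fit
        other = MultiTaskGPRegressor(Q=1, rank=1, n_iter=120, random_state=0).fit(X, Z)
        assert np.array_equal(other.theta_, model.theta_)
        xs = np.array([[0.2, 0.4]])
        assert np.array_equal(other.predict(xs), model.predict(xs))

    def test_serialization_round_trip_is_exact(self, toy_fit, tmp_path):
        X, Z, model = toy_fit
        p = tmp_path / "model.json"
        model.save(p)
        loaded = MultiTaskGPRegressor.load(p)
        xs = np.random.default_rng(0).uniform(0, 1, (9, 2))
        m0, c0 = model.predict(xs, return_cov=True)
        m1, c1 = loaded.predict(xs, return_cov=True)
        assert np.array_equal(m0, m1) and np.array_equal(c0, c1)

    def test_input_validation(self):
        est = MultiTaskGPRegressor()
        with pytest.raises(ValueError, match="at least 10"):
            est.fit(np.zeros((4, 2)), np.zeros((4, 2)))
        with pytest.raises(ValueError, match="rank"):
            MultiTaskGPRegressor(rank=5).fit(np.random.rand(12, 2), np.random.rand(12, 2))
        with pytest.raises(ValueError, match="number of samples"):
            est.fit(np.zeros((12, 2)), np.zeros((11, 2)))
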