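"""Multi-task Gaussian process regression over 2-D coordinates.

The model couples M water properties through a joint covariance

    cov(f_k(x), f_l(x')) = K^f_{kl} · k^x(x − x'),

with a spectral-mixture spatial kernel k^x, a low-rank-plus-diagonal task
covariance K^f = B Bᵀ + diag(v), a quadratic polynomial mean per task and
diagonal Gaussian observation noise D.  Hyper-parameters are estimated by
maximum marginal likelihood (Adam on an unconstrained reparameterization,
with component length-scales box-constrained to avoid over-fitting).

Prediction exploits the Kronecker structure of Σ = K^f ⊗ K^x + D ⊗ I via a
pair of symmetric eigendecompositions (O(N³ + M³) once, then O(NM) per
location for the mean and O(NM + M³) for the covariance); a naive dense
path over the full NM×NM system is kept for cross-checking and small
problems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from scipy.linalg import cho_solve, eigh
from scipy.spatial import cKDTree
from sklearn.base import BaseEstimator, RegressorMixin

from . import _mll
from .kernels import (
    DEFAULT_LENGTHSCALE_BOX,
    MeanPolyCoeffs,
    SMKernelParams,
    correlation_from_task_cov,
    lengthscale_to_variance,
    quad_basis,
    quadratic_mean,
    sm_kernel_matrix,
    task_covariance,
)

__all__ = [
    "MultiTaskGPRegressor",
    "PredictiveDistribution",
    "fit_model",
    "predict",
    "neg_log_marginal_likelihood",
]


@dataclass
class PredictiveDistribution:
    """M-variate Gaussian predictive law at one location (warped space)."""

    location: np.ndarray
    mean: np.ndarray
    covariance: np.ndarray


def neg_log_marginal_likelihood(
    X,
    Z,
    kernel: SMKernelParams,
    B,
    vtask,
    noise,
    mean_coeffs: MeanPolyCoeffs,
) -> float:
    """−log p(Z | X, θ) of the multi-task model (dense evaluation).

    ``Z`` is (N, M); the flattened observation vector is task-major, matching
    Σ = K^f ⊗ K^x + D ⊗ I_N.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    N, M = Z.shape
    Kx = sm_kernel_matrix(X, X, kernel)
    Kf = task_covariance(B, vtask)
    sigma = np.kron(Kf, Kx) + np.kron(np.diag(np.asarray(noise, float)), np.eye(N))
    cf, _ = _mll.chol_with_jitter(sigma)
    res = (Z - quadratic_mean(X, mean_coeffs)).T.reshape(-1)
    alpha = cho_solve(cf, res)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    return 0.5 * float(res @ alpha) + 0.5 * logdet + 0.5 * N * M * _mll.LOG_2PI


class MultiTaskGPRegressor(RegressorMixin, BaseEstimator):
    """Multi-task GP regressor with SM kernel and low-rank task covariance.

    Parameters
    ----------
    Q:
        Number of spectral mixture components.
    rank:
        Rank r of the low-rank part of the task covariance.
    lengthscale_box:
        Closed interval confining every component length-scale (in scaled
        coordinate units); guards against over-fitting.
    n_iter, learning_rate:
        Adam iterations / step size for the marginal-likelihood ascent.
    init_lengthscale:
        Initial component length-scale (scaled units).
    random_state:
        Seed controlling initialization; fits are bit-for-bit reproducible.
    """

    def __init__(
        self,
        Q: int = 1,
        rank: int = 2,
        lengthscale_box: Tuple[float, float] = DEFAULT_LENGTHSCALE_BOX,
        n_iter: int = 300,
        learning_rate: float = 0.1,
        init_lengthscale: float = 0.3,
        random_state: int = 0,
    ):
        self.Q = Q
        self.rank = rank
        self.lengthscale_box = lengthscale_box
        self.n_iter = n_iter
        self.learning_rate = learning_rate
        self.init_lengthscale = init_lengthscale
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def _initial_theta(self, X, Z, packing) -> np.ndarray:
        rng = np.random.default_rng(self.random_state)
        N, M = Z.shape
        sl = packing.slices
        theta = np.zeros(packing.size)
        total_var = float(Z.var())
        total_var = max(total_var, 1e-6)
        theta[sl["w"]] = _mll.inv_softplus(np.full(self.Q, total_var / self.Q))
        lo, hi = self.lengthscale_box
        ell0 = float(np.clip(self.init_lengthscale, lo * (1 + 1e-9), hi * (1 - 1e-9)))
        theta[sl["ell"]] = _mll.logit((ell0 - lo) / (hi - lo))
        # spectral means uniform in [0, Nyquist] of the typical point spacing
        tree = cKDTree(X)
        dist, _ = tree.query(X, k=2)
        spacing = float(np.median(dist[:, 1]))
        nyquist = 0.5 / max(spacing, 1e-6)
        theta[sl["mu"]] = rng.uniform(0.0, nyquist, size=self.Q * 2)
        task_var = np.maximum(Z.var(axis=0), 1e-6)
        theta[sl["B"]] = rng.normal(
            0.0, np.sqrt(0.5 * total_var / self.rank), size=M * self.rank
        )
        theta[sl["vtask"]] = _mll.inv_softplus(0.5 * task_var)
        theta[sl["noise"]] = _mll.inv_softplus(0.1 * task_var)
        C = np.zeros((6, M))
        C[0] = Z.mean(axis=0)
        theta[sl["mean"]] = C.reshape(-1)
        return theta

    def fit(self, X, Z):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if X.shape[0] != Z.shape[0]:
            raise ValueError("X and Z disagree on the number of samples")
        if X.shape[0] < 10:
            raise ValueError("need at least 10 training samples")
        if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Z))):
            raise ValueError("non-finite training values")
        N, M = Z.shape
        if self.rank > M:
            raise ValueError(f"rank {self.rank} exceeds the number of tasks {M}")
        packing = _mll.Packing(Q=self.Q, M=M, r=self.rank)
        box = tuple(float(b) for b in self.lengthscale_box)
        theta0 = self._initial_theta(X, Z, packing)

        def fun_grad(theta):
            return _mll.nll_grad(theta, X, Z, packing, box)

        theta, best_val, trace = _mll.adam_minimize(
            fun_grad, theta0, n_iter=self.n_iter, lr=self.learning_rate
        )
        p = _mll.unpack(theta, packing, box)
        self.packing_ = packing
        self.theta_ = theta
        self.nll_ = best_val
        self.trace_ = trace
        self.kernel_params_ = SMKernelParams(
            weights=p["w"], means=p["mu"], variances=p["v"], lengthscale_box=box
        )
        self.mean_coeffs_ = MeanPolyCoeffs(p["C"])
        self.task_cov_B_ = p["B"]
        self.task_cov_v_ = p["vtask"]
        self.noise_ = p["noise"]
        self.Kf_ = task_covariance(p["B"], p["vtask"])
        self.X_train_ = X
        self.Z_train_ = Z
        self.n_features_in_ = 2
        self._pred_cache = None
        return self

    # ------------------------------------------------------------ prediction
    @property
    def task_correlation_(self) -> np.ndarray:
        """Pearson correlations between tasks implied by the fitted K^f."""
        return correlation_from_task_cov(self.Kf_)

    def _cache(self):
        """Eigendecomposition cache for the Kronecker solve."""
        if self._pred_cache is not None:
            return self._pred_cache
        X, Z = self.X_train_, self.Z_train_
        N, M = Z.shape
        Kx = sm_kernel_matrix(X, X, self.kernel_params_)
        dm12 = 1.0 / np.sqrt(self.noise_)
        Kf_t = dm12[:, None] * self.Kf_ * dm12[None, :]
        lam_f, Uf = eigh(Kf_t)
        lam_x, Ux = eigh(Kx)
        denom = lam_f[:, None] * lam_x[None, :] + 1.0  # (M, N)
        res_mat = (Z - quadratic_mean(X, self.mean_coeffs_)).T  # (M, N)
        r1 = dm12[:, None] * res_mat
        r2 = (Uf.T @ r1) @ Ux / denom
        amat = dm12[:, None] * (Uf @ r2 @ Ux.T)  # Σ⁻¹ residual, (M, N)
        A = Uf.T @ (dm12[:, None] * self.Kf_)  # (M, M)
        self._pred_cache = dict(
            Kx=Kx, amat=amat, A=A, lam_f=lam_f, lam_x=lam_x, Ux=Ux, denom=denom
        )
        return self._pred_cache

    def _predict_kron(self, Xs: np.ndarray):
        c = self._cache()
        kstar = sm_kernel_matrix(self.X_train_, Xs, self.kernel_params_)  # (N, B)
        mean = quadratic_mean(Xs, self.mean_coeffs_) + (self.Kf_ @ (c["amat"] @ kstar)).T
        kxx = float(np.sum(self.kernel_params_.weights))
        t = c["Ux"].T @ kstar  # (N, B)
        s_all = (1.0 / c["denom"]) @ (t**2)  # (M, B)
        covs = kxx * self.Kf_[None, :, :] - np.einsum(
            "al,am,ab->blm", c["A"], c["A"], s_all
        )
        covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))
        return mean, covs

    def _predict_dense(self, Xs: np.ndarray):
        X, Z = self.X_train_, self.Z_train_
        N, M = Z.shape
        Kx = sm_kernel_matrix(X, X, self.kernel_params_)
        sigma = np.kron(self.Kf_, Kx) + np.kron(np.diag(self.noise_), np.eye(N))
        cf, _ = _mll.chol_with_jitter(sigma)
        res = (Z - quadratic_mean(X, self.mean_coeffs_)).T.reshape(-1)
        alpha = cho_solve(cf, res)
        kxx = float(np.sum(self.kernel_params_.weights))
        kstar = sm_kernel_matrix(X, Xs, self.kernel_params_)
        mean = np.empty((Xs.shape[0], M))
        covs = np.empty((Xs.shape[0], M, M))
        mu_s = quadratic_mean(Xs, self.mean_coeffs_)
        for b in range(Xs.shape[0]):
            H = np.kron(self.Kf_, kstar[:, b][:, None])  # (NM, M), task-major
            mean[b] = mu_s[b] + H.T @ alpha
            SH = cho_solve(cf, H)
            cov = kxx * self.Kf_ - H.T @ SH
            covs[b] = 0.5 * (cov + cov.T)
        return mean, covs

    def predict(
        self,
        X,
        return_cov: bool = False,
        method: str = "kron",
        batch_size: Optional[int] = 1024,
    ):
        """Predictive mean (n, M) and optionally covariances (n, M, M).

        Both live in the warped target space.  ``method`` selects the
        Kronecker eigensolve (default) or the dense NM×NM fallback; the two
        agree to numerical precision.
        """
        Xs = np.atleast_2d(np.asarray(X, dtype=float))
        if method not in ("kron", "dense"):
            raise ValueError(f"unknown prediction method {method!r}")
        fn = self._predict_kron if method == "kron" else self._predict_dense
        if batch_size is None or Xs.shape[0] <= batch_size:
            mean, covs = fn(Xs)
        else:
            means, covss = [], []
            for start in range(0, Xs.shape[0], batch_size):
                m, cv = fn(Xs[start : start + batch_size])
                means.append(m)
                covss.append(cv)
            mean, covs = np.vstack(means), np.concatenate(covss, axis=0)
        return (mean, covs) if return_cov else mean

    def predict_distributions(
        self, X, method: str = "kron", batch_size: Optional[int] = 1024
    ) -> List[PredictiveDistribution]:
        Xs = np.atleast_2d(np.asarray(X, dtype=float))
        mean, covs = self.predict(Xs, return_cov=True, method=method, batch_size=batch_size)
        return [
            PredictiveDistribution(location=Xs[i], mean=mean[i], covariance=covs[i])
            for i in range(Xs.shape[0])
        ]

    @classmethod
    def from_parameters(
        cls,
        X,
        Z,
        kernel: SMKernelParams,
        B,
        vtask,
        noise,
        mean_coeffs: MeanPolyCoeffs,
    ) -> "MultiTaskGPRegressor":
        """Build a 'fitted' model from prescribed hyper-parameters (no training)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        B = np.atleast_2d(np.asarray(B, dtype=float))
        est = cls(Q=kernel.Q, rank=B.shape[1], lengthscale_box=kernel.lengthscale_box)
        est.packing_ = _mll.Packing(Q=kernel.Q, M=Z.shape[1], r=B.shape[1])
        est.theta_ = None
        est.nll_ = np.nan
        est.trace_ = np.asarray([])
        est.kernel_params_ = kernel
        est.mean_coeffs_ = mean_coeffs
        est.task_cov_B_ = B
        est.task_cov_v_ = np.asarray(vtask, dtype=float)
        est.noise_ = np.asarray(noise, dtype=float)
        est.Kf_ = task_covariance(B, vtask)
        est.X_train_ = X
        est.Z_train_ = Z
        est.n_features_in_ = 2
        est._pred_cache = None
        return est

    # --------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "params": self.get_params(),
            "theta": self.theta_.tolist(),
            "X_train": self.X_train_.tolist(),
            "Z_train": self.Z_train_.tolist(),
            "nll": self.nll_,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MultiTaskGPRegressor":
        params = dict(payload["params"])
        params["lengthscale_box"] = tuple(params["lengthscale_box"])
        est = cls(**params)
        X = np.asarray(payload["X_train"], dtype=float)
        Z = np.asarray(payload["Z_train"], dtype=float)
        packing = _mll.Packing(Q=est.Q, M=Z.shape[1], r=est.rank)
        theta = np.asarray(payload["theta"], dtype=float)
        p = _mll.unpack(theta, packing, est.lengthscale_box)
        est.packing_ = packing
        est.theta_ = theta
        est.nll_ = payload["nll"]
        est.trace_ = np.asarray([])
        est.kernel_params_ = SMKernelParams(
            weights=p["w"], means=p["mu"], variances=p["v"],
            lengthscale_box=est.lengthscale_box,
        )
        est.mean_coeffs_ = MeanPolyCoeffs(p["C"])
        est.task_cov_B_ = p["B"]
        est.task_cov_v_ = p["vtask"]
        est.noise_ = p["noise"]
        est.Kf_ = task_covariance(p["B"], p["vtask"])
        est.X_train_ = X
        est.Z_train_ = Z
        est.n_features_in_ = 2
        est._pred_cache = None
        return est

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "MultiTaskGPRegressor":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_model(X, Z, Q: int = 1, r: int = 2, seed: int = 0, **optimizer) -> MultiTaskGPRegressor:
    """Fit a multi-task GP with the given mixture size and task-cov rank."""
    return MultiTaskGPRegressor(Q=Q, rank=r, random_state=seed, **optimizer).fit(X, Z)


def predict(model: MultiTaskGPRegressor, X, **kw) -> List[PredictiveDistribution]:
    """Per-location predictive distributions (warped space)."""
    return model.predict_distributions(X, **kw)
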