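"""Spectral mixture kernel, low-rank task covariance and quadratic mean.

The spatial kernel is the spectral mixture (SM) kernel

    k(τ) = Σ_q w_q Π_p exp(−2π² τ_p² v_p^(q)) cos(2π τ_p μ_p^(q)),

a weighted mixture of Q Gaussians in the frequency domain that can
approximate any stationary kernel.  The inter-parameter covariance is the
low-rank-plus-diagonal (intrinsic coregionalization) form

    K^f = B Bᵀ + diag(v),    B ∈ R^{M×r},  v > 0,

and the mean is a full quadratic polynomial in the two scaled coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np

__all__ = [
    "SMKernelParams",
    "MeanPolyCoeffs",
    "sm_kernel",
    "sm_kernel_matrix",
    "task_covariance",
    "quadratic_mean",
    "correlation_from_task_cov",
    "lengthscale_to_variance",
    "variance_to_lengthscale",
]

DEFAULT_LENGTHSCALE_BOX: Tuple[float, float] = (0.1, 100.0)


def lengthscale_to_variance(ell):
    """Spectral variance of a component with length-scale ℓ: v = 1/(4π²ℓ²)."""
    ell = np.asarray(ell, dtype=float)
    return 1.0 / (4.0 * np.pi**2 * ell**2)


def variance_to_lengthscale(v):
    """Inverse of :func:`lengthscale_to_variance`: ℓ = 1/(2π√v)."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (2.0 * np.pi * np.sqrt(v))


@dataclass
class SMKernelParams:
    """Hyper-parameters of a spectral mixture kernel in d dimensions.

    ``weights`` has shape (Q,); ``means`` and ``variances`` have shape
    (Q, d).  The length-scale 1/(2π√v) of every component must lie inside
    ``lengthscale_box``.
    """

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    lengthscale_box: Tuple[float, float] = DEFAULT_LENGTHSCALE_BOX

    def __post_init__(self):
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=float))
        q = self.weights.shape[0]
        if self.means.shape[0] != q or self.variances.shape[0] != q:
            raise ValueError("weights, means and variances disagree on Q")
        if self.means.shape != self.variances.shape:
            raise ValueError("means and variances disagree on shape")
        if np.any(self.weights <= 0):
            raise ValueError("mixture weights must be positive")
        if np.any(self.variances <= 0):
            raise ValueError("spectral variances must be positive")

    @property
    def Q(self) -> int:
        return self.weights.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def lengthscales(self) -> np.ndarray:
        return variance_to_lengthscale(self.variances)


@dataclass
class MeanPolyCoeffs:
    """Coefficients of μ(x) = c0 + c1·x1 + c2·x2 + c12·x1x2 + c11·x1² + c22·x2².

    ``coeffs`` is a (6, M) array, rows ordered (c0, c1, c2, c12, c11, c22).
    """

    coeffs: np.ndarray

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2 or self.coeffs.shape[0] != 6:
            raise ValueError("expected a (6, M) coefficient array")


def quad_basis(X: np.ndarray) -> np.ndarray:
    """Design matrix (n, 6) of the quadratic mean at 2-D inputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    x1, x2 = X[:, 0], X[:, 1]
    return np.column_stack([np.ones_like(x1), x1, x2, x1 * x2, x1**2, x2**2])


def quadratic_mean(X: np.ndarray, coeffs: MeanPolyCoeffs) -> np.ndarray:
    """Evaluate the quadratic mean at n points → (n, M) matrix."""
    return quad_basis(X) @ coeffs.coeffs


def sm_kernel(tau, params: SMKernelParams):
    """Evaluate the SM kernel at coordinate differences τ ((..., d) array)."""
    tau = np.asarray(tau, dtype=float)
    scalar_d = tau.ndim == 1
    t = np.atleast_2d(tau)[..., None, :]  # (..., 1, d)
    w, mu, v = params.weights, params.means, params.variances
    factors = np.exp(-2.0 * np.pi**2 * t**2 * v) * np.cos(2.0 * np.pi * t * mu)
    k = np.sum(w * np.prod(factors, axis=-1), axis=-1)
    return float(k[0]) if scalar_d else k


def sm_kernel_matrix(X1: np.ndarray, X2: np.ndarray, params: SMKernelParams) -> np.ndarray:
    """Gram matrix k(x_i − x_j) between two point sets ((n1, d), (n2, d))."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    tau = X1[:, None, :] - X2[None, :, :]
    return sm_kernel(tau, params)


def task_covariance(B: np.ndarray, v: np.ndarray) -> np.ndarray:
    """K^f = B Bᵀ + diag(v) with positive v (symmetric positive definite)."""
    B = np.atleast_2d(np.asarray(B, dtype=float))
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("diagonal task variances must be positive")
    if B.shape[0] != v.shape[0]:
        raise ValueError("B and v disagree on the number of tasks")
    return B @ B.T + np.diag(v)


def correlation_from_task_cov(Kf: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the task covariance K^f."""
    Kf = np.asarray(Kf, dtype=float)
    d = np.diag(Kf)
    if np.any(d <= 0):
        raise ValueError("task covariance has a non-positive diagonal entry")
    s = np.sqrt(d)
    rho = Kf / np.outer(s, s)
    np.fill_diagonal(rho, 1.0)
    return rho
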