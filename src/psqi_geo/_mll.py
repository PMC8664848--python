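"""Marginal likelihood of the multi-task GP and its analytic gradient.

The joint covariance of the N·M flattened (task-major) observation vector is

    Σ = K^f ⊗ K^x + D ⊗ I_N,

with K^x the spectral-mixture Gram matrix on the N training locations,
K^f = B Bᵀ + diag(v) the task covariance and D the diagonal noise.  The
negative log marginal likelihood and its gradient with respect to the raw
(unconstrained) parameter vector are computed densely — exact Cholesky,
no approximations — with the Kronecker structure exploited so that the
gradient costs O(M²N²) rather than O(#params · M²N²).

Raw parameterization
--------------------
* mixture weights, task diagonal, noise: softplus
* component length-scales: logistic map onto the configured box, with the
  spectral variance v = 1/(4π²ℓ²)
* spectral means, B, mean-polynomial coefficients: unconstrained
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .kernels import quad_basis

LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# scalar reparameterizations
# ---------------------------------------------------------------------------

def softplus(x):
    return np.logaddexp(0.0, x)


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def inv_softplus(y):
    y = np.asarray(y, dtype=float)
    return np.where(y > 20, y, np.log(np.expm1(np.clip(y, 1e-12, None))))


def logit(p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


# ---------------------------------------------------------------------------
# parameter packing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Packing:
    """Layout of the raw parameter vector for given (Q, M, r), d = 2."""

    Q: int
    M: int
    r: int
    d: int = 2

    @property
    def slices(self) -> Dict[str, slice]:
        Q, M, r, d = self.Q, self.M, self.r, self.d
        sizes = [
            ("w", Q),
            ("ell", Q * d),
            ("mu", Q * d),
            ("B", M * r),
            ("vtask", M),
            ("noise", M),
            ("mean", 6 * M),
        ]
        out, start = {}, 0
        for name, size in sizes:
            out[name] = slice(start, start + size)
            start += size
        return out

    @property
    def size(self) -> int:
        sl = self.slices["mean"]
        return sl.stop


def unpack(theta: np.ndarray, packing: Packing, box: Tuple[float, float]):
    """Raw vector → natural parameters (dict)."""
    sl = packing.slices
    Q, M, r, d = packing.Q, packing.M, packing.r, packing.d
    lo, hi = box
    raw_ell = theta[sl["ell"]].reshape(Q, d)
    ell = lo + (hi - lo) * sigmoid(raw_ell)
    return {
        "w": softplus(theta[sl["w"]]),
        "ell": ell,
        "v": 1.0 / (4.0 * np.pi**2 * ell**2),
        "mu": theta[sl["mu"]].reshape(Q, d),
        "B": theta[sl["B"]].reshape(M, r),
        "vtask": softplus(theta[sl["vtask"]]),
        "noise": softplus(theta[sl["noise"]]),
        "C": theta[sl["mean"]].reshape(6, M),
    }


# ---------------------------------------------------------------------------
# kernel evaluation with cached per-component factors
# ---------------------------------------------------------------------------

def _kernel_factors(tau: np.ndarray, w, v, mu):
    """Per-(q, p) factors of the SM kernel on a difference tensor (..., d)."""
    # tau: (n1, n2, d); broadcast to (Q, n1, n2, d)
    t = tau[None, ...]
    E = np.exp(-2.0 * np.pi**2 * t**2 * v[:, None, None, :])
    Cs = np.cos(2.0 * np.pi * t * mu[:, None, None, :])
    F = E * Cs  # (Q, n1, n2, d)
    prod = np.prod(F, axis=-1)  # (Q, n1, n2)
    K = np.tensordot(w, prod, axes=(0, 0))
    return K, F, E, prod


def sm_gram(X1, X2, w, v, mu):
    tau = X1[:, None, :] - X2[None, :, :]
    K, _, _, _ = _kernel_factors(tau, w, v, mu)
    return K


# ---------------------------------------------------------------------------
# Cholesky with escalating jitter
# ---------------------------------------------------------------------------

def chol_with_jitter(sigma: np.ndarray, base: float = 1e-6, max_jitter: float = 1e-2):
    """Cholesky factor of a symmetric matrix, adding diagonal jitter on failure."""
    try:
        return cho_factor(sigma, lower=True), 0.0
    except LinAlgError:
        pass
    jitter = base
    eye = np.eye(sigma.shape[0])
    while jitter <= max_jitter * (1 + 1e-12):
        try:
            return cho_factor(sigma + jitter * eye, lower=True), jitter
        except LinAlgError:
            jitter *= 10.0
    raise LinAlgError(
        f"covariance is not positive definite even with jitter {max_jitter:g}"
    )


# ---------------------------------------------------------------------------
# negative log marginal likelihood + gradient
# ---------------------------------------------------------------------------

def nll(theta, X, Z, packing: Packing, box) -> float:
    return nll_grad(theta, X, Z, packing, box, want_grad=False)[0]


def nll_grad(theta, X, Z, packing: Packing, box, want_grad: bool = True):
    """Return (negative log marginal likelihood, gradient wrt raw vector).

    ``X`` is (N, 2) scaled coordinates, ``Z`` is (N, M) warped targets.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    N, M = Z.shape
    Q, r, d = packing.Q, packing.r, packing.d
    p = unpack(theta, packing, box)
    sl = packing.slices
    lo, hi = box

    tau = X[:, None, :] - X[None, :, :]
    Kx, F, E, prod = _kernel_factors(tau, p["w"], p["v"], p["mu"])
    B, vtask, noise = p["B"], p["vtask"], p["noise"]
    Kf = B @ B.T + np.diag(vtask)

    sigma = np.kron(Kf, Kx) + np.kron(np.diag(noise), np.eye(N))
    cf, _ = chol_with_jitter(sigma)

    phi = quad_basis(X)  # (N, 6)
    mean_mat = phi @ p["C"]  # (N, M)
    res = (Z - mean_mat).T.reshape(-1)  # task-major NM vector

    alpha = cho_solve(cf, res)
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    value = 0.5 * float(res @ alpha) + 0.5 * logdet + 0.5 * N * M * LOG_2PI
    if not want_grad:
        return value, None

    P = cho_solve(cf, np.eye(N * M))  # Σ⁻¹
    P4 = P.reshape(M, N, M, N)
    amat = alpha.reshape(M, N)

    # shared contractions
    T_kern = np.einsum("kilj,lk->ij", P4, Kf)          # for dΣ = K^f ⊗ dK^x
    S_kern = amat.T @ Kf @ amat                          # (N, N)
    T_task = np.einsum("kilj,ij->kl", P4, Kx)           # for dΣ = dK^f ⊗ K^x
    V_task = amat @ Kx @ amat.T                          # (M, M)
    G_kern = 0.5 * (T_kern - S_kern)                     # grad = sum(G_kern * dKx)
    G_task = 0.5 * (T_task - V_task)                     # grad = sum(G_task * dKf)

    grad = np.zeros_like(theta)

    # --- spectral mixture parameters ---
    raw_w = theta[sl["w"]]
    dw = sigmoid(raw_w)  # d softplus
    gw = np.empty(Q)
    g_ell = np.empty((Q, d))
    g_mu = np.empty((Q, d))
    raw_ell = theta[sl["ell"]].reshape(Q, d)
    sig_ell = sigmoid(raw_ell)
    dell_draw = (hi - lo) * sig_ell * (1 - sig_ell)
    dv_dell = -2.0 * p["v"] / p["ell"]
    for q in range(Q):
        gw[q] = np.sum(G_kern * prod[q]) * dw[q]
        for pp in range(d):
            other = F[q, :, :, 1 - pp] if d == 2 else np.prod(
                np.delete(F[q], pp, axis=-1), axis=-1
            )
            dK_dv = p["w"][q] * (-2.0 * np.pi**2 * tau[:, :, pp] ** 2) * prod[q]
            g_ell[q, pp] = np.sum(G_kern * dK_dv) * dv_dell[q, pp] * dell_draw[q, pp]
            dC = -2.0 * np.pi * tau[:, :, pp] * np.sin(
                2.0 * np.pi * tau[:, :, pp] * p["mu"][q, pp]
            )
            dK_dmu = p["w"][q] * other * E[q, :, :, pp] * dC
            g_mu[q, pp] = np.sum(G_kern * dK_dmu)
    grad[sl["w"]] = gw
    grad[sl["ell"]] = g_ell.reshape(-1)
    grad[sl["mu"]] = g_mu.reshape(-1)

    # --- task covariance: dK^f/dB_mj = e_m b_jᵀ + b_j e_mᵀ ---
    grad[sl["B"]] = (2.0 * G_task @ B).reshape(-1)
    grad[sl["vtask"]] = np.diag(G_task) * sigmoid(theta[sl["vtask"]])

    # --- noise: dΣ = (e_k e_kᵀ) ⊗ I ---
    diag_blocks = np.einsum("kiki->k", P4)
    grad[sl["noise"]] = 0.5 * (diag_blocks - np.sum(amat**2, axis=1)) * sigmoid(
        theta[sl["noise"]]
    )

    # --- mean coefficients ---
    grad[sl["mean"]] = (-(phi.T @ amat.T)).reshape(-1)

    return value, grad


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

def adam_minimize(fun_grad, theta0, n_iter=300, lr=0.1, beta1=0.9, beta2=0.999,
                  eps=1e-8, callback=None):
    """Plain Adam; returns the best iterate seen and the loss trace."""
    theta = np.array(theta0, dtype=float)
    m = np.zeros_like(theta)
    s = np.zeros_like(theta)
    best_theta, best_val = theta.copy(), np.inf
    trace = []
    for it in range(1, n_iter + 1):
        val, grad = fun_grad(theta)
        if not np.isfinite(val) or not np.all(np.isfinite(grad)):
            raise RuntimeError(f"optimization diverged (non-finite loss/gradient) at iteration {it}")
        trace.append(val)
        if val < best_val:
            best_val, best_theta = val, theta.copy()
        m = beta1 * m + (1 - beta1) * grad
        s = beta2 * s + (1 - beta2) * grad**2
        mh = m / (1 - beta1**it)
        sh = s / (1 - beta2**it)
        theta = theta - lr * mh / (np.sqrt(sh) + eps)
        if callback is not None:
            callback(it, val, theta)
    # evaluate the final iterate too
    val, _ = fun_grad(theta)
    if np.isfinite(val):
        trace.append(val)
        if val < best_val:
            best_val, best_theta = val, theta.copy()
    return best_theta, best_val, np.asarray(trace)
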