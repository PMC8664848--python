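"""Probabilistic Substance Quality Index (PSQI) and its confidence metric.

At a location x* the model yields an M-variate Gaussian predictive law in
warped measurement space.  For each regulated property i, with admissible
range [b_i^L, b_i^U],

    p̂_i(x*) = P( b_i^L ≤ z_i ≤ b_i^U ),   all other components marginalized,

and the index aggregates these with normalized weights:

    PSQI(x*) = Σ_i w_i p̂_i(x*)  ∈ [0, 1].

Marginalizing an M-variate Gaussian over all-but-one coordinate gives the
i-th univariate marginal exactly, so p̂_i is the difference of two normal
CDF values — no numerical integration is needed (a full multivariate
integration is retained only as a test oracle).

The companion confidence metric recomputes the same weighted mass with the
mean recentred at the interval midpoints: it is high when the predictive
spread is small relative to the admissible range, irrespective of where
the mean sits, and equals PSQI exactly when the mean is already at the
midpoints.

Weights default to a softmax of the (clamped) cross-validation R² scores,
w_i ∝ exp(max(R²_i, 0)), so poorly modeled properties contribute less.
Properties whose R² is non-positive fall back to the training-set marginal
(dataset mean and variance, correlations zeroed); unregulated properties
are excluded from the index altogether.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.special import ndtr

from .mtgpr import PredictiveDistribution
from .preprocess import BoundedWarper
from .standards import EXCLUDED, StandardsTable, effective_bounds

__all__ = [
    "PSQIWeights",
    "PSQIResult",
    "marginal_probability",
    "softmax_weights",
    "apply_fallback",
    "psqi_value",
    "confidence_value",
    "fraction_in_bounds",
    "PSQICalculator",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PSQIWeights:
    """Normalized per-parameter importance weights."""

    names: Tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.names),):
            raise ValueError("weights and names disagree on length")
        if np.any(v <= 0) or abs(v.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be positive and sum to 1")
        object.__setattr__(self, "values", v)

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(self.names, self.values))


@dataclass
class PSQIResult:
    """Index and confidence at one location, with per-parameter marginals."""

    location: np.ndarray
    psqi: float
    confidence: float
    marginals: Dict[str, float]
    confidence_marginals: Dict[str, float]
    weights: PSQIWeights


def _gauss_interval_mass(mean: float, var: float, lo: float, hi: float) -> float:
    """P(lo ≤ Z ≤ hi) for Z ~ N(mean, var); indicator when var degenerates."""
    if var <= 0:
        return float(lo <= mean <= hi)
    sd = math.sqrt(var)
    return float(ndtr((hi - mean) / sd) - ndtr((lo - mean) / sd))


def marginal_probability(
    pred: PredictiveDistribution, i: int, bounds: Tuple[float, float]
) -> float:
    """Probability that component i lies in ``bounds``, others integrated out.

    Exact closed form: the i-th marginal of a multivariate Gaussian is the
    univariate N(mean_i, cov_ii).
    """
    lo, hi = bounds
    if not lo < hi:
        raise ValueError(f"degenerate bounds ({lo}, {hi})")
    return _gauss_interval_mass(float(pred.mean[i]), float(pred.covariance[i, i]), lo, hi)


def softmax_weights(r2: Mapping[str, Optional[float]]) -> PSQIWeights:
    """w_i = exp(max(R²_i, 0)) / Σ_j exp(max(R²_j, 0)).

    Negative (or missing) scores behave exactly as zero.
    """
    if not r2:
        raise ValueError("cannot build weights from an empty parameter set")
    names = tuple(r2.keys())
    scores = np.array(
        [max(float(v), 0.0) if v is not None and np.isfinite(v) else 0.0 for v in r2.values()]
    )
    e = np.exp(scores - scores.max())  # stable softmax; shift cancels
    return PSQIWeights(names=names, values=e / e.sum())


def apply_fallback(
    pred: PredictiveDistribution,
    r2: Sequence[Optional[float]],
    dataset_mean: np.ndarray,
    dataset_var: np.ndarray,
) -> PredictiveDistribution:
    """Replace poorly modeled components by the dataset marginal (warped space).

    For every parameter with R² ≤ 0 (or undefined): predictive mean ← dataset
    mean, variance ← dataset variance, and all its covariances with other
    parameters ← 0.  Well-modeled entries are untouched; the result stays
    symmetric positive semi-definite.
    """
    mean = np.array(pred.mean, dtype=float)
    cov = np.array(pred.covariance, dtype=float)
    for i, score in enumerate(r2):
        if score is None or not np.isfinite(score) or score <= 0:
            mean[i] = dataset_mean[i]
            cov[i, :] = 0.0
            cov[:, i] = 0.0
            cov[i, i] = dataset_var[i]
    return PredictiveDistribution(location=pred.location, mean=mean, covariance=cov)


def _warped_sd_to_naive(
    warper: BoundedWarper, mean_w: np.ndarray, sd_w: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Original-space (mean, sd) pretending the law were Gaussian there.

    Used only by the documented 'naive' integration mode: the central value
    is the inverse-warped mean and the spread is half the inverse-warped
    ±1 sd interval.
    """
    m = warper.inverse_transform(mean_w[None, :])[0]
    hi = warper.inverse_transform((mean_w + sd_w)[None, :])[0]
    lo = warper.inverse_transform((mean_w - sd_w)[None, :])[0]
    return m, 0.5 * (hi - lo)


class PSQICalculator:
    """Vectorized PSQI/confidence evaluation for a fixed model setup.

    Parameters
    ----------
    standards, warper:
        Regulatory table and the fitted warp; together they fix which
        parameters enter the index and the warped integration intervals.
    weights:
        Normalized weights over the regulated parameters (default: softmax
        of ``r2_scores``; uniform if neither is given).
    r2_scores:
        Per-parameter cross-validation R² (original space).  Drives both the
        softmax weights and the dataset-marginal fallback for R² ≤ 0.
    space:
        ``"warped"`` (probability-preserving, default) integrates the
        Gaussian against warped bounds; ``"naive"`` pretends the predictive
        law is Gaussian in original units.
    """

    def __init__(
        self,
        standards: StandardsTable,
        warper: BoundedWarper,
        weights: Optional[PSQIWeights] = None,
        r2_scores: Optional[Mapping[str, Optional[float]]] = None,
        reweight: Optional[Mapping[str, float]] = None,
        space: str = "warped",
    ):
        if space not in ("warped", "naive"):
            raise ValueError(f"unknown integration space {space!r}")
        self.standards = standards
        self.warper = warper
        self.space = space
        names = warper.feature_names_in_
        regulated = [
            n for n in names
            if n in standards and effective_bounds(standards[n]) is not EXCLUDED
        ]
        if not regulated:
            raise ValueError("no regulated parameters available for the index")
        self.regulated = tuple(regulated)
        self.indices = np.array([names.index(n) for n in regulated])
        self.bounds_orig = np.array(
            [effective_bounds(standards[n]) for n in regulated], dtype=float
        )
        wb = warper.warp_bounds(standards)
        self.bounds_warped = np.array([wb[n] for n in regulated])
        if weights is None:
            if r2_scores is not None:
                weights = softmax_weights({n: r2_scores.get(n) for n in regulated})
            else:
                weights = softmax_weights({n: 0.0 for n in regulated})
        if tuple(weights.names) != self.regulated:
            raise ValueError("weights must cover exactly the regulated parameters, in order")
        if reweight:
            v = weights.values * np.array([reweight.get(n, 1.0) for n in regulated])
            weights = PSQIWeights(names=self.regulated, values=v / v.sum())
        self.weights = weights
        self.r2 = (
            np.array(
                [
                    r2_scores.get(n) if r2_scores.get(n) is not None else np.nan
                    for n in regulated
                ],
                dtype=float,
            )
            if r2_scores is not None
            else np.ones(len(regulated))
        )
        self._fallback_mask = ~(np.nan_to_num(self.r2, nan=-1.0) > 0)
        self.dataset_mean_: Optional[np.ndarray] = None
        self.dataset_var_: Optional[np.ndarray] = None

    def set_dataset_stats(self, Z_train: np.ndarray) -> "PSQICalculator":
        """Record warped-space dataset means/variances for the fallback."""
        Z = np.asarray(Z_train, dtype=float)
        self.dataset_mean_ = Z.mean(axis=0)[self.indices]
        self.dataset_var_ = Z.var(axis=0)[self.indices]
        return self

    def evaluate(self, mean: np.ndarray, covs: np.ndarray):
        """PSQI, confidence and marginals for a batch of predictive laws.

        ``mean`` is (n, M) and ``covs`` (n, M, M), both in warped space.
        Returns ``(psqi, conf, p, q)`` with shapes (n,), (n,), (n, k), (n, k)
        over the k regulated parameters.
        """
        mean = np.atleast_2d(np.asarray(mean, dtype=float))
        covs = np.asarray(covs, dtype=float)
        m = mean[:, self.indices]
        var = covs[:, self.indices, self.indices]
        if np.any(self._fallback_mask):
            if self.dataset_mean_ is None:
                raise ValueError(
                    "parameters with non-positive R² require dataset statistics; "
                    "call set_dataset_stats first"
                )
            m = m.copy()
            var = var.copy()
            m[:, self._fallback_mask] = self.dataset_mean_[self._fallback_mask]
            var[:, self._fallback_mask] = self.dataset_var_[self._fallback_mask]
        var = np.maximum(var, 0.0)
        sd = np.sqrt(var)
        if self.space == "warped":
            lo = self.bounds_warped[:, 0]
            hi = self.bounds_warped[:, 1]
        else:
            lo = self.bounds_orig[:, 0]
            hi = self.bounds_orig[:, 1]
            full_m = mean.copy()
            full_sd = np.zeros_like(full_m)
            full_sd[:, self.indices] = sd
            m_list, s_list = [], []
            for row_m, row_s in zip(full_m, full_sd):
                mm, ss = _warped_sd_to_naive(self.warper, row_m, row_s)
                m_list.append(mm[self.indices])
                s_list.append(ss[self.indices])
            m = np.array(m_list)
            sd = np.array(s_list)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(
                sd > 0,
                ndtr((hi - m) / sd) - ndtr((lo - m) / sd),
                ((lo <= m) & (m <= hi)).astype(float),
            )
            mid = 0.5 * (lo + hi)
            q = np.where(
                sd > 0,
                ndtr((hi - mid) / sd) - ndtr((lo - mid) / sd),
                1.0,
            )
        w = self.weights.values
        return p @ w, q @ w, p, q

    def result_at(self, pred: PredictiveDistribution) -> PSQIResult:
        psqi, conf, p, q = self.evaluate(pred.mean[None, :], pred.covariance[None, :, :])
        return PSQIResult(
            location=pred.location,
            psqi=float(psqi[0]),
            confidence=float(conf[0]),
            marginals=dict(zip(self.regulated, p[0])),
            confidence_marginals=dict(zip(self.regulated, q[0])),
            weights=self.weights,
        )


def psqi_value(
    pred: PredictiveDistribution,
    standards: StandardsTable,
    warper: BoundedWarper,
    weights: Optional[PSQIWeights] = None,
    **kw,
) -> PSQIResult:
    """PSQI at a single predictive distribution (see :class:`PSQICalculator`)."""
    calc = PSQICalculator(standards, warper, weights=weights, **kw)
    return calc.result_at(pred)


def confidence_value(
    pred: PredictiveDistribution,
    standards: StandardsTable,
    warper: BoundedWarper,
    weights: Optional[PSQIWeights] = None,
    **kw,
) -> float:
    """Confidence companion of :func:`psqi_value` (same weights and bounds)."""
    return psqi_value(pred, standards, warper, weights=weights, **kw).confidence


def fraction_in_bounds(row: Mapping[str, float], standards: StandardsTable) -> float:
    """Fraction of regulated parameters whose measured value is in bounds.

    Missing values are skipped (dropped from numerator and denominator) with
    a warning; unregulated parameters never count.
    """
    num = den = 0
    for spec in standards:
        bounds = effective_bounds(spec)
        if bounds is EXCLUDED or spec.name not in row:
            continue
        val = row[spec.name]
        if val is None or (isinstance(val, float) and np.isnan(val)):
            logger.warning("missing value for %s; skipped in fraction_in_bounds", spec.name)
            continue
        den += 1
        if bounds[0] <= float(val) <= bounds[1]:
            num += 1
    if den == 0:
        raise ValueError("no regulated parameters with values in this row")
    return num / den
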