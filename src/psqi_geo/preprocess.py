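"""Input normalization: coordinate scaling and bounded-measurement warping.

Two scikit-learn transformers implement the data normalization stage:

* :class:`CoordinateScaler` — projects (longitude, latitude) degrees to a
  metric transverse-Mercator plane and min-max scales the training extent
  to the unit square.  GP length-scales are expressed in these units.
* :class:`BoundedWarper` — maps non-negative, bounded concentrations into
  a space where a Gaussian model is appropriate: min-max scaling by
  generous per-parameter limits, exact zeros replaced by ``1e-10``, the
  standard-normal inverse CDF, and a second min-max scaling to [0, 1].
  The map is strictly increasing and invertible, so rectangle
  probabilities computed in warped space equal the corresponding
  original-space probabilities.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator, TransformerMixin

from .projection import TransverseMercator, utm_epsg_for
from .standards import StandardsTable, effective_bounds, EXCLUDED

__all__ = [
    "CoordinateScaler",
    "BoundedWarper",
    "read_samples",
    "ZERO_REPLACEMENT",
]

#: Value substituted for exact zeros (in the min-max-scaled unit interval)
#: before the inverse normal CDF is applied.
ZERO_REPLACEMENT = 1e-10

#: Relative inward clamping margin applied to prediction-time values that
#: sit on or beyond the scaling limits (the inverse CDF diverges at 0 and 1).
_CLAMP_MARGIN = 1e-12


class CoordinateScaler(BaseEstimator, TransformerMixin):
    """Project lon/lat degrees to metres and scale the training extent to [0,1]².

    Parameters
    ----------
    epsg:
        UTM zone EPSG code (e.g. 32637).  When ``None`` the zone containing
        the centroid of the training points is used.
    """

    def __init__(self, epsg: Optional[int] = None):
        self.epsg = epsg

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("expected an (n, 2) array of (longitude, latitude)")
        if X.shape[0] < 2:
            raise ValueError("need at least two points to fit the scaler")
        epsg = self.epsg
        if epsg is None:
            epsg = utm_epsg_for(float(np.mean(X[:, 0])), float(np.mean(X[:, 1])))
        self.projection_ = TransverseMercator(epsg)
        e, n = self.projection_.forward(X[:, 0], X[:, 1])
        self.min_xy_ = np.array([e.min(), n.min()])
        self.max_xy_ = np.array([e.max(), n.max()])
        if np.any(self.max_xy_ - self.min_xy_ <= 0):
            raise ValueError("degenerate spatial extent: all points share a coordinate")
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        e, n = self.projection_.forward(X[:, 0], X[:, 1])
        span = self.max_xy_ - self.min_xy_
        return (np.column_stack([e, n]) - self.min_xy_) / span

    def inverse_transform(self, X):
        X = np.asarray(X, dtype=float)
        span = self.max_xy_ - self.min_xy_
        en = X * span + self.min_xy_
        lon, lat = self.projection_.inverse(en[:, 0], en[:, 1])
        return np.column_stack([lon, lat])


def _as_matrix(Y, names: Sequence[str]) -> np.ndarray:
    if isinstance(Y, pd.DataFrame):
        return Y.loc[:, list(names)].to_numpy(dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[1] != len(names):
        raise ValueError(f"expected {len(names)} parameter columns, got {Y.shape[1]}")
    return Y


class BoundedWarper(BaseEstimator, TransformerMixin):
    """Invertible map between bounded measurements and the unit model space.

    Per parameter, the fitted forward map is

        u = (y - lo) / (up - lo);  u==0 → 1e-10;  g = Φ⁻¹(u);
        z = (g - g_min) / (g_max - g_min)

    with ``up = 10·max{y_max, b_U}`` (``b_U`` the regulatory upper bound)
    or the hard physical domain when one is declared (pH: [0, 14]), and
    ``g_min``/``g_max`` the post-ICDF extrema of the training column.

    Parameters
    ----------
    standards:
        Table supplying regulatory upper bounds and hard domains.  Columns
        of the fitted data must be a subset of the table's parameters; a
        DataFrame fixes the column order, a bare array is assumed to follow
        the table's order.
    """

    def __init__(self, standards: Optional[StandardsTable] = None):
        self.standards = standards

    def _names(self, Y) -> Tuple[str, ...]:
        if isinstance(Y, pd.DataFrame):
            return tuple(Y.columns)
        if self.standards is not None:
            return self.standards.names
        raise ValueError("a standards table or a DataFrame with named columns is required")

    def fit(self, Y, y=None):
        names = self._names(Y)
        mat = _as_matrix(Y, names)
        if not np.all(np.isfinite(mat)):
            raise ValueError("non-finite measurement values")
        if np.any(mat < 0):
            raise ValueError("negative measurement values are not allowed")
        self.feature_names_in_ = names
        m = len(names)
        lower = np.zeros(m)
        upper = np.empty(m)
        for j, name in enumerate(names):
            spec = self.standards[name] if (
                self.standards is not None and name in self.standards
            ) else None
            col_max = float(mat[:, j].max())
            if spec is not None and spec.hard_domain is not None:
                # bounded physical support (pH-style): use it verbatim, no 10x
                lower[j], upper[j] = spec.hard_domain
                if col_max > upper[j] or float(mat[:, j].min()) < lower[j]:
                    raise ValueError(f"{name}: values outside hard domain {spec.hard_domain}")
            else:
                b_up = spec.normative_upper if spec is not None else None
                base = max(col_max, b_up if b_up is not None else 0.0)
                if base <= 0:
                    base = 1.0  # all-zero unregulated column
                upper[j] = 10.0 * base
        self.lower_limit_ = lower
        self.upper_limit_ = upper
        g = self._icdf_stage(mat)
        self.stage2_min_ = g.min(axis=0)
        self.stage2_max_ = g.max(axis=0)
        degenerate = self.stage2_max_ - self.stage2_min_ <= 0
        if np.any(degenerate):
            # constant column: give the affine stage unit slope around the value
            self.stage2_min_ = np.where(degenerate, self.stage2_min_ - 0.5, self.stage2_min_)
            self.stage2_max_ = np.where(degenerate, self.stage2_max_ + 0.5, self.stage2_max_)
        return self

    def _icdf_stage(self, mat: np.ndarray) -> np.ndarray:
        u = (mat - self.lower_limit_) / (self.upper_limit_ - self.lower_limit_)
        u = np.where(u <= 0, ZERO_REPLACEMENT, u)
        u = np.clip(u, ZERO_REPLACEMENT, 1.0 - _CLAMP_MARGIN)
        return ndtri(u)

    def transform(self, Y):
        mat = _as_matrix(Y, self.feature_names_in_)
        g = self._icdf_stage(mat)
        return (g - self.stage2_min_) / (self.stage2_max_ - self.stage2_min_)

    def inverse_transform(self, Z):
        Z = np.asarray(Z, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        g = Z * (self.stage2_max_ - self.stage2_min_) + self.stage2_min_
        u = ndtr(g)
        return self.lower_limit_ + u * (self.upper_limit_ - self.lower_limit_)

    # -- scalar helpers ---------------------------------------------------
    def _col(self, name: str) -> int:
        try:
            return self.feature_names_in_.index(name)
        except ValueError:
            raise KeyError(name) from None

    def warp_value(self, name: str, y: float) -> float:
        """Forward-map a single original-space value of one parameter."""
        j = self._col(name)
        row = np.zeros((1, len(self.feature_names_in_)))
        row[0, j] = y
        return float(self.transform(row)[0, j])

    def warp_bounds(self, standards: Optional[StandardsTable] = None) -> Dict[str, Tuple[float, float]]:
        """Regulatory intervals mapped into warped space.

        A lower bound of 0 maps through the zero-replacement value, exactly
        as a measured zero would.  Unregulated parameters are omitted.
        """
        standards = standards if standards is not None else self.standards
        out: Dict[str, Tuple[float, float]] = {}
        for name in self.feature_names_in_:
            if name not in standards:
                continue
            bounds = effective_bounds(standards[name])
            if bounds is EXCLUDED:
                continue
            zlo = self.warp_value(name, bounds[0])
            zhi = self.warp_value(name, bounds[1])
            if not zlo < zhi:
                raise ValueError(f"{name}: degenerate warped interval ({zlo}, {zhi})")
            out[name] = (zlo, zhi)
        return out


def read_samples(
    path,
    standards: Optional[StandardsTable] = None,
) -> pd.DataFrame:
    """Read a samples CSV (``longitude,latitude,<param>...``).

    When a standards table is given, parameter columns are restricted to
    and reordered by the table; unknown extra columns are dropped.
    """
    frame = pd.read_csv(path)
    for col in ("longitude", "latitude"):
        if col not in frame.columns:
            raise ValueError(f"samples file {path}: missing column {col!r}")
    if standards is not None:
        params = [n for n in standards.names if n in frame.columns]
        if not params:
            raise ValueError(f"samples file {path}: no parameter columns match the standards table")
        frame = frame[["longitude", "latitude", *params]]
    return frame
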