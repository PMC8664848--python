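"""Cross-validated model scoring and (Q, r) selection.

Models are compared by the coefficient of determination R² = 1 − MSE/Var,
computed per water property *in original measurement units* (predictions
are inverse-warped first; the warp is nonlinear, so warped-space R² would
differ).  Five seeded random 80/20 train/test splits are used by default;
a disjoint 5-fold mode is available.  Properties whose split-averaged R²
is negative for every candidate model are masked out, and the model with
the highest mean over the kept properties and splits wins (ties go to the
simpler model: smaller Q, then smaller r).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .mtgpr import MultiTaskGPRegressor
from .preprocess import BoundedWarper, CoordinateScaler
from .standards import StandardsTable

__all__ = ["CVReport", "r2_original_space", "cross_validate", "mask_and_select",
           "write_reports"]

logger = logging.getLogger(__name__)


def r2_original_space(y_true, y_pred) -> Optional[float]:
    """R² = 1 − MSE/Var(y_true); ``None`` when the test variance is zero."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("expected two equal-length vectors")
    if y_true.size < 2:
        raise ValueError("need at least two test values")
    var = float(np.var(y_true))
    if var == 0.0:
        return None
    mse = float(np.mean((y_true - y_pred) ** 2))
    return 1.0 - mse / var


@dataclass
class CVReport:
    """Per-split, per-parameter R² scores of one (Q, r) candidate."""

    Q: int
    r: int
    param_names: Tuple[str, ...]
    r2: np.ndarray  # (n_splits, M), NaN where undefined or the split failed
    failed_splits: Tuple[int, ...] = ()

    @property
    def per_param_mean(self) -> np.ndarray:
        """Split-averaged R² per parameter (NaN cells excluded)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.r2, axis=0)

    def overall_mean(self, kept: Optional[Sequence[str]] = None) -> float:
        """Mean over all splits and (kept) parameters."""
        cols = (
            [self.param_names.index(n) for n in kept]
            if kept is not None
            else list(range(len(self.param_names)))
        )
        cells = self.r2[:, cols]
        return float(np.nanmean(cells))


def _split_indices(n: int, n_splits: int, train_frac: float, seed: int, mode: str):
    if mode == "resample":
        rng = np.random.default_rng(seed)
        n_train = int(round(train_frac * n))
        for _ in range(n_splits):
            perm = rng.permutation(n)
            yield perm[:n_train], perm[n_train:]
    elif mode == "kfold":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        for fold in np.array_split(perm, n_splits):
            test = np.sort(fold)
            train = np.setdiff1d(perm, test)
            yield train, test
    else:
        raise ValueError(f"unknown CV mode {mode!r}")


def cross_validate(
    samples: pd.DataFrame,
    standards: StandardsTable,
    Q: int,
    r: int,
    seed: int = 0,
    n_splits: int = 5,
    train_frac: float = 0.8,
    mode: str = "resample",
    epsg: Optional[int] = None,
    **fit_options,
) -> CVReport:
    """Cross-validate one (Q, r) candidate on a geo-referenced samples table.

    The coordinate scaler and the warp are fitted on each training fold only;
    R² is computed in original measurement units on the test fold.  A fold
    whose fit fails is recorded and skipped with a warning, never silently
    averaged.
    """
    param_names = tuple(c for c in samples.columns if c not in ("longitude", "latitude"))
    lonlat = samples[["longitude", "latitude"]].to_numpy(dtype=float)
    Y = samples.loc[:, list(param_names)]
    n = len(samples)
    n_test_min = n - int(round(train_frac * n))
    if n_test_min < 5:
        raise ValueError("dataset too small: each test fold needs at least 5 points")

    scores = np.full((n_splits, len(param_names)), np.nan)
    failed: List[int] = []
    for s, (tr, te) in enumerate(_split_indices(n, n_splits, train_frac, seed, mode)):
        try:
            scaler = CoordinateScaler(epsg=epsg).fit(lonlat[tr])
            warper = BoundedWarper(standards).fit(Y.iloc[tr])
            model = MultiTaskGPRegressor(Q=Q, rank=r, random_state=seed, **fit_options)
            model.fit(scaler.transform(lonlat[tr]), warper.transform(Y.iloc[tr]))
            z_pred = model.predict(scaler.transform(lonlat[te]))
            y_pred = warper.inverse_transform(z_pred)
        except Exception as exc:  # noqa: BLE001 - fold failures are data-driven
            logger.warning("split %d failed for (Q=%d, r=%d): %s", s, Q, r, exc)
            failed.append(s)
            continue
        y_true = Y.iloc[te].to_numpy(dtype=float)
        for j in range(len(param_names)):
            val = r2_original_space(y_true[:, j], y_pred[:, j])
            scores[s, j] = np.nan if val is None else val
    return CVReport(Q=Q, r=r, param_names=param_names, r2=scores,
                    failed_splits=tuple(failed))


def mask_and_select(
    reports: Sequence[CVReport],
    exclude: Iterable[str] = (),
) -> Tuple[Tuple[str, ...], CVReport]:
    """Mask poorly modeled parameters and pick the best (Q, r).

    A parameter is dropped iff the maximum over candidate models of its
    split-averaged R² is negative; parameters in ``exclude`` (chronically
    poor by prior inspection) are dropped unconditionally.  The winner
    maximizes the mean R² over kept parameters and splits; exact ties break
    toward smaller Q, then smaller r.
    """
    if not reports:
        raise ValueError("need at least one CV report")
    names = reports[0].param_names
    for rep in reports:
        if rep.param_names != names:
            raise ValueError("CV reports disagree on parameter names")
    per_param = np.vstack([rep.per_param_mean for rep in reports])  # (models, M)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        best_per_param = np.nanmax(per_param, axis=0)
    kept = tuple(
        n
        for j, n in enumerate(names)
        if n not in set(exclude) and np.isfinite(best_per_param[j]) and best_per_param[j] >= 0
    )
    if not kept:
        raise ValueError("every parameter was masked out; no model can be selected")
    ordered = sorted(reports, key=lambda rep: (rep.Q, rep.r))
    best = max(ordered, key=lambda rep: rep.overall_mean(kept))
    return kept, best


def write_reports(reports: Sequence[CVReport], csv_path, summary_path=None,
                  exclude: Iterable[str] = ()) -> None:
    """Dump CV scores as tidy CSV plus a YAML summary (mask and best model)."""
    rows = []
    for rep in reports:
        for s in range(rep.r2.shape[0]):
            for j, name in enumerate(rep.param_names):
                val = rep.r2[s, j]
                rows.append(
                    {"Q": rep.Q, "r": rep.r, "split": s, "parameter": name,
                     "r2": None if np.isnan(val) else float(val)}
                )
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if summary_path is not None:
        kept, best = mask_and_select(reports, exclude=exclude)
        summary = {
            "kept_parameters": list(kept),
            "masked_parameters": [n for n in reports[0].param_names if n not in kept],
            "best_model": {"Q": int(best.Q), "r": int(best.r),
                           "mean_r2": best.overall_mean(kept)},
            "per_parameter_mean_r2": {
                n: float(v) if np.isfinite(v) else None
                for n, v in zip(best.param_names, best.per_param_mean)
            },
        }
        with open(summary_path, "w") as fh:
            yaml.safe_dump(summary, fh, sort_keys=False)
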