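"""End-to-end bundle: coordinate scaler + warp + multi-task GP + index.

:class:`WaterQualityModel` glues the fitted pieces together so that maps
and index values can be produced from raw (longitude, latitude) queries,
and serializes the whole state to a single self-describing JSON file from
which predictions are reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .mtgpr import MultiTaskGPRegressor
from .preprocess import BoundedWarper, CoordinateScaler
from .projection import TransverseMercator
from .psqi import PSQICalculator, PSQIWeights
from .standards import ParameterSpec, StandardsTable

__all__ = ["WaterQualityModel"]


def _standards_to_records(table: StandardsTable):
    return [
        {
            "name": s.name,
            "unit": s.unit,
            "lower": s.normative_lower,
            "upper": s.normative_upper,
            "hard_lower": None if s.hard_domain is None else s.hard_domain[0],
            "hard_upper": None if s.hard_domain is None else s.hard_domain[1],
        }
        for s in table
    ]


def _standards_from_records(records) -> StandardsTable:
    specs = []
    for r in records:
        hard = (
            (r["hard_lower"], r["hard_upper"])
            if r["hard_lower"] is not None and r["hard_upper"] is not None
            else None
        )
        specs.append(ParameterSpec(r["name"], r["unit"], r["lower"], r["upper"], hard))
    return StandardsTable(specs)


@dataclass
class WaterQualityModel:
    """Fitted water-quality model over one region and one standards table."""

    standards: StandardsTable
    scaler: CoordinateScaler
    warper: BoundedWarper
    model: MultiTaskGPRegressor
    r2_scores: Optional[Dict[str, Optional[float]]] = None
    fingerprint: Optional[str] = None

    @classmethod
    def fit(
        cls,
        samples: pd.DataFrame,
        standards: StandardsTable,
        Q: int = 1,
        r: int = 2,
        seed: int = 0,
        epsg: Optional[int] = None,
        r2_scores: Optional[Mapping[str, Optional[float]]] = None,
        **fit_options,
    ) -> "WaterQualityModel":
        """Fit scaler, warp and GP on the full samples table."""
        params = [c for c in samples.columns if c not in ("longitude", "latitude")]
        lonlat = samples[["longitude", "latitude"]].to_numpy(dtype=float)
        scaler = CoordinateScaler(epsg=epsg).fit(lonlat)
        warper = BoundedWarper(standards).fit(samples.loc[:, params])
        model = MultiTaskGPRegressor(Q=Q, rank=r, random_state=seed, **fit_options)
        model.fit(scaler.transform(lonlat), warper.transform(samples.loc[:, params]))
        fp = hashlib.sha256(
            samples.to_csv(index=False).encode()
        ).hexdigest()
        return cls(
            standards=standards,
            scaler=scaler,
            warper=warper,
            model=model,
            r2_scores=dict(r2_scores) if r2_scores is not None else None,
            fingerprint=fp,
        )

    @property
    def param_names(self) -> Tuple[str, ...]:
        return self.warper.feature_names_in_

    def predict_warped(self, lonlat, **kw):
        """Warped-space predictive mean/covariances at lon/lat queries."""
        X = self.scaler.transform(np.atleast_2d(np.asarray(lonlat, dtype=float)))
        return self.model.predict(X, return_cov=True, **kw)

    def calculator(self, space: str = "warped",
                   weights: Optional[PSQIWeights] = None,
                   reweight: Optional[Mapping[str, float]] = None) -> PSQICalculator:
        """Index calculator wired to this model's warp, R² scores and data."""
        calc = PSQICalculator(
            self.standards, self.warper, weights=weights,
            r2_scores=self.r2_scores, reweight=reweight, space=space,
        )
        calc.set_dataset_stats(self.model.Z_train_)
        return calc

    # ----------------------------------------------------------- persistence
    def to_dict(self) -> dict:
        return {
            "format": "psqi-geo/model",
            "version": 1,
            "standards": _standards_to_records(self.standards),
            "scaler": {
                "epsg": self.scaler.projection_.epsg,
                "min_xy": self.scaler.min_xy_.tolist(),
                "max_xy": self.scaler.max_xy_.tolist(),
            },
            "warper": {
                "feature_names": list(self.warper.feature_names_in_),
                "lower_limit": self.warper.lower_limit_.tolist(),
                "upper_limit": self.warper.upper_limit_.tolist(),
                "stage2_min": self.warper.stage2_min_.tolist(),
                "stage2_max": self.warper.stage2_max_.tolist(),
            },
            "model": self.model.to_dict(),
            "r2_scores": self.r2_scores,
            "fingerprint": self.fingerprint,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "WaterQualityModel":
        standards = _standards_from_records(payload["standards"])
        scaler = CoordinateScaler(epsg=payload["scaler"]["epsg"])
        scaler.projection_ = TransverseMercator(payload["scaler"]["epsg"])
        scaler.min_xy_ = np.asarray(payload["scaler"]["min_xy"], dtype=float)
        scaler.max_xy_ = np.asarray(payload["scaler"]["max_xy"], dtype=float)
        warper = BoundedWarper(standards)
        w = payload["warper"]
        warper.feature_names_in_ = tuple(w["feature_names"])
        warper.lower_limit_ = np.asarray(w["lower_limit"], dtype=float)
        warper.upper_limit_ = np.asarray(w["upper_limit"], dtype=float)
        warper.stage2_min_ = np.asarray(w["stage2_min"], dtype=float)
        warper.stage2_max_ = np.asarray(w["stage2_max"], dtype=float)
        model = MultiTaskGPRegressor.from_dict(payload["model"])
        return cls(
            standards=standards,
            scaler=scaler,
            warper=warper,
            model=model,
            r2_scores=payload.get("r2_scores"),
            fingerprint=payload.get("fingerprint"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "WaterQualityModel":
        return cls.from_dict(json.loads(Path(path).read_text()))
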