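"""Uniform prediction grids and batch map products.

A grid is an axis-aligned lattice in projected metres (default spacing
100 m — roughly one point per 100 m cell), endpoints inclusive, optionally
filtered to a polygon.  ``predict_map`` evaluates the predictive
distribution, the quality index and its confidence at every grid point and
exports CSV / GeoJSON point products.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, shape

from .projection import TransverseMercator, utm_epsg_for
from .pipeline import WaterQualityModel

__all__ = ["GridSpec", "make_grid", "predict_map", "write_geojson", "load_region"]

BBox = Tuple[float, float, float, float]  # lon1, lat1, lon2, lat2


@dataclass
class GridSpec:
    """Region (bbox degrees or polygon in EPSG:4326) + lattice spacing in metres."""

    region: Union[BBox, Polygon]
    spacing: float = 100.0
    batch_size: int = 4096

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def polygon(self) -> Optional[Polygon]:
        return self.region if isinstance(self.region, Polygon) else None

    @property
    def bbox(self) -> BBox:
        if self.polygon is not None:
            lon1, lat1, lon2, lat2 = self.polygon.bounds
            return (lon1, lat1, lon2, lat2)
        lon1, lat1, lon2, lat2 = self.region
        return (min(lon1, lon2), min(lat1, lat2), max(lon1, lon2), max(lat1, lat2))


def load_region(path) -> Polygon:
    """Read a GeoJSON file and return its (first) polygon in EPSG:4326."""
    payload = json.loads(Path(path).read_text())
    if payload.get("type") == "FeatureCollection":
        geom = payload["features"][0]["geometry"]
    elif payload.get("type") == "Feature":
        geom = payload["geometry"]
    else:
        geom = payload
    poly = shape(geom)
    if not isinstance(poly, Polygon):
        raise ValueError(f"expected a Polygon region, got {poly.geom_type}")
    return poly


def _axis(lo: float, hi: float, spacing: float) -> np.ndarray:
    n = int(np.floor((hi - lo) / spacing + 1e-9)) + 1
    return lo + spacing * np.arange(n)


def make_grid(spec: GridSpec, epsg: Optional[int] = None) -> pd.DataFrame:
    """Inclusive lattice over the region → DataFrame (longitude, latitude, easting, northing).

    The lattice is built in projected metres (UTM zone of the region centroid
    unless ``epsg`` is given) and filtered to the polygon, boundary included,
    when one is supplied.
    """
    lon1, lat1, lon2, lat2 = spec.bbox
    if epsg is None:
        epsg = utm_epsg_for(0.5 * (lon1 + lon2), 0.5 * (lat1 + lat2))
    proj = TransverseMercator(epsg)
    (e1, n1) = proj.forward(lon1, lat1)
    (e2, n2) = proj.forward(lon2, lat2)
    es = _axis(min(e1, e2), max(e1, e2), spec.spacing)
    ns = _axis(min(n1, n2), max(n1, n2), spec.spacing)
    ee, nn = np.meshgrid(es, ns, indexing="ij")
    lon, lat = proj.inverse(ee.ravel(), nn.ravel())
    frame = pd.DataFrame(
        {"longitude": lon, "latitude": lat, "easting": ee.ravel(), "northing": nn.ravel()}
    )
    poly = spec.polygon
    if poly is not None:
        keep = [
            poly.covers(Point(lo, la))
            for lo, la in zip(frame["longitude"], frame["latitude"])
        ]
        frame = frame.loc[keep].reset_index(drop=True)
    if len(frame) == 0:
        raise ValueError("empty grid: region is smaller than the requested spacing")
    return frame


def predict_map(
    wqm: WaterQualityModel,
    grid: pd.DataFrame,
    space: str = "warped",
    batch_size: Optional[int] = None,
) -> pd.DataFrame:
    """Evaluate predictions and the quality index at every grid point.

    Output columns: longitude, latitude, ``mean_<param>`` (original units,
    the inverse-warp of the warped predictive mean — a median-type central
    estimate), ``sd_warped_<param>`` (spread in warped space), ``psqi``,
    ``confidence`` and per-regulated-parameter marginals ``p_<param>`` /
    ``q_<param>``.
    """
    lonlat = grid[["longitude", "latitude"]].to_numpy(dtype=float)
    calc = wqm.calculator(space=space)
    names = wqm.param_names
    batch = batch_size or 4096
    frames = []
    for start in range(0, len(lonlat), batch):
        chunk = lonlat[start : start + batch]
        try:
            mean_w, covs = wqm.predict_warped(chunk, batch_size=None)
        except Exception as exc:
            raise RuntimeError(
                f"prediction failed for batch starting at row {start}: {exc}"
            ) from exc
        psqi, conf, p, q = calc.evaluate(mean_w, covs)
        mean_orig = wqm.warper.inverse_transform(mean_w)
        sd_w = np.sqrt(np.maximum(covs[:, np.arange(len(names)), np.arange(len(names))], 0.0))
        data = {
            "longitude": chunk[:, 0],
            "latitude": chunk[:, 1],
            **{f"mean_{n}": mean_orig[:, j] for j, n in enumerate(names)},
            **{f"sd_warped_{n}": sd_w[:, j] for j, n in enumerate(names)},
            "psqi": psqi,
            "confidence": conf,
            **{f"p_{n}": p[:, j] for j, n in enumerate(calc.regulated)},
            **{f"q_{n}": q[:, j] for j, n in enumerate(calc.regulated)},
        }
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True)


def write_geojson(map_table: pd.DataFrame, path) -> None:
    """Write the map table as a GeoJSON FeatureCollection of points."""
    props = [c for c in map_table.columns if c not in ("longitude", "latitude")]
    features = [
        {
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [float(row["longitude"]), float(row["latitude"])],
            },
            "properties": {c: float(row[c]) for c in props},
        }
        for _, row in map_table.iterrows()
    ]
    payload = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(payload))
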