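"""Geographic ↔ projected (UTM / transverse Mercator) coordinate conversion.

Implements the Karney–Krüger series for the transverse Mercator projection
on the WGS84 ellipsoid, truncated at sixth order in the third flattening
``n`` — sub-millimetre accuracy anywhere within a UTM zone and far beyond.
EPSG codes 32601–32660 (north) and 32701–32760 (south) are supported; the
zone can also be picked automatically from the data centroid.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TransverseMercator", "utm_epsg_for", "project", "unproject"]

# WGS84
_A = 6378137.0
_F = 1.0 / 298.257223563
_E = np.sqrt(_F * (2.0 - _F))
_N = _F / (2.0 - _F)

# Krüger series coefficients, sixth order in n (Karney 2011, Eqs. 35–36).
_n = _N
_ALPHA = np.array([
    _n / 2 - 2 * _n**2 / 3 + 5 * _n**3 / 16 + 41 * _n**4 / 180
    - 127 * _n**5 / 288 + 7891 * _n**6 / 37800,
    13 * _n**2 / 48 - 3 * _n**3 / 5 + 557 * _n**4 / 1440
    + 281 * _n**5 / 630 - 1983433 * _n**6 / 1935360,
    61 * _n**3 / 240 - 103 * _n**4 / 140 + 15061 * _n**5 / 26880
    + 167603 * _n**6 / 181440,
    49561 * _n**4 / 161280 - 179 * _n**5 / 168 + 6601661 * _n**6 / 7257600,
    34729 * _n**5 / 80640 - 3418889 * _n**6 / 1995840,
    212378941 * _n**6 / 319334400,
])
_BETA = np.array([
    _n / 2 - 2 * _n**2 / 3 + 37 * _n**3 / 96 - _n**4 / 360
    - 81 * _n**5 / 512 + 96199 * _n**6 / 604800,
    _n**2 / 48 + _n**3 / 15 - 437 * _n**4 / 1440
    + 46 * _n**5 / 105 - 1118711 * _n**6 / 3870720,
    17 * _n**3 / 480 - 37 * _n**4 / 840 - 209 * _n**5 / 4480
    + 5569 * _n**6 / 90720,
    4397 * _n**4 / 161280 - 11 * _n**5 / 504 - 830251 * _n**6 / 7257600,
    4583 * _n**5 / 161280 - 108847 * _n**6 / 3991680,
    20648693 * _n**6 / 638668800,
])
# Rectifying radius
_AA = _A / (1 + _N) * (1 + _N**2 / 4 + _N**4 / 64 + _N**6 / 256)

_K0 = 0.9996
_FALSE_E = 500000.0


def utm_epsg_for(lon: float, lat: float) -> int:
    """EPSG code of the UTM zone containing the point (lon, lat in degrees)."""
    zone = int(np.floor((lon + 180.0) / 6.0)) % 60 + 1
    return (32600 if lat >= 0 else 32700) + zone


class TransverseMercator:
    """UTM-style transverse Mercator projection identified by an EPSG code."""

    def __init__(self, epsg: int):
        if 32601 <= epsg <= 32660:
            zone, south = epsg - 32600, False
        elif 32701 <= epsg <= 32760:
            zone, south = epsg - 32700, True
        else:
            raise ValueError(f"unsupported EPSG code {epsg}: expected a UTM zone 326xx/327xx")
        self.epsg = epsg
        self.lon0 = np.deg2rad(zone * 6.0 - 183.0)
        self.false_northing = 10000000.0 if south else 0.0

    def forward(self, lon, lat):
        """Degrees (lon, lat) → projected metres (easting, northing)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 360):
            raise ValueError("longitude/latitude outside valid ranges")
        phi = np.deg2rad(lat)
        dlam = np.deg2rad(lon) - self.lon0
        s = np.sin(phi)
        # conformal latitude
        t = np.sinh(np.arctanh(s) - _E * np.arctanh(_E * s))
        xi_p = np.arctan2(t, np.cos(dlam))
        eta_p = np.arcsinh(np.sin(dlam) / np.hypot(t, np.cos(dlam)))
        j = np.arange(1, 7)
        xi = xi_p + np.sum(
            _ALPHA * np.sin(2 * j * xi_p[..., None]) * np.cosh(2 * j * eta_p[..., None]),
            axis=-1,
        )
        eta = eta_p + np.sum(
            _ALPHA * np.cos(2 * j * xi_p[..., None]) * np.sinh(2 * j * eta_p[..., None]),
            axis=-1,
        )
        easting = _FALSE_E + _K0 * _AA * eta
        northing = self.false_northing + _K0 * _AA * xi
        return easting, northing

    def inverse(self, easting, northing):
        """Projected metres → degrees (lon, lat)."""
        easting = np.asarray(easting, dtype=float)
        northing = np.asarray(northing, dtype=float)
        xi = (northing - self.false_northing) / (_K0 * _AA)
        eta = (easting - _FALSE_E) / (_K0 * _AA)
        j = np.arange(1, 7)
        xi_p = xi - np.sum(
            _BETA * np.sin(2 * j * xi[..., None]) * np.cosh(2 * j * eta[..., None]),
            axis=-1,
        )
        eta_p = eta - np.sum(
            _BETA * np.cos(2 * j * xi[..., None]) * np.sinh(2 * j * eta[..., None]),
            axis=-1,
        )
        tau_p = np.sin(xi_p) / np.hypot(np.sinh(eta_p), np.cos(xi_p))
        lam = np.arctan2(np.sinh(eta_p), np.cos(xi_p))
        # invert the conformal latitude by fixed point (contraction ~ e^2)
        psi = np.arcsinh(tau_p)
        phi = np.arctan(tau_p)
        for _ in range(8):
            phi = np.arctan(np.sinh(psi + _E * np.arctanh(_E * np.sin(phi))))
        return np.rad2deg(lam + self.lon0), np.rad2deg(phi)


def project(lon, lat, epsg: int):
    """Functional form of :meth:`TransverseMercator.forward`."""
    return TransverseMercator(epsg).forward(lon, lat)


def unproject(easting, northing, epsg: int):
    """Functional form of :meth:`TransverseMercator.inverse`."""
    return TransverseMercator(epsg).inverse(easting, northing)
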