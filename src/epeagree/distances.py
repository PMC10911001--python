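"""Pluggable point-to-point distance conventions.

Synthetic regions live on a planar km frame; real lon/lat extracts use
great-circle haversine distance on a sphere of radius 6371.0088 km.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def euclidean_km(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Pairwise planar distances in km.

    Parameters are (n, 2) and (m, 2) arrays of x/y km; returns (n, m).
    """
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    d = a[:, None, :] - b[None, :, :]
    return np.hypot(d[..., 0], d[..., 1])


def haversine_km(points_a: np.ndarray, points_b: np.ndarray) -> np.ndarray:
    """Pairwise great-circle distances in km for (lon, lat) degree pairs."""
    a = np.radians(np.atleast_2d(np.asarray(points_a, dtype=float)))
    b = np.radians(np.atleast_2d(np.asarray(points_b, dtype=float)))
    lon1, lat1 = a[:, None, 0], a[:, None, 1]
    lon2, lat2 = b[None, :, 0], b[None, :, 1]
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_distances(points_a, points_b, crs: str = "planar_km") -> np.ndarray:
    """Dispatch on the coordinate convention ('planar_km' or 'lonlat')."""
    if crs == "planar_km":
        return euclidean_km(points_a, points_b)
    if crs == "lonlat":
        return haversine_km(points_a, points_b)
    raise ValueError(f"unknown crs {crs!r}")
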