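"""Great-circle route metrics: haversine distance, route length, detour index.

Distances use the haversine formula on a sphere of mean radius 6371 km; the
route detour index is the ratio of summed leg distances to the direct
great-circle distance between the route endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "RouteSummary",
    "haversine",
    "route_distance",
    "detour_index",
    "summarize_route",
]


@dataclass(frozen=True)
class RouteSummary:
    endpoint_distance_km: float
    route_distance_km: float
    detour_index: float | None  # None when endpoints coincide


def _check_points(lat, lon):
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
        raise ValueError("coordinates out of bounds (|lat|<=90, |lon|<=180)")
    return lat, lon


def haversine(p1, p2, earth_radius_km: float = EARTH_RADIUS_KM):
    """Great-circle distance in km between (lat, lon) points in degrees.

    Accepts scalars or broadcastable arrays; returns km.
    """
    lat1, lon1 = _check_points(p1[0], p1[1])
    lat2, lon2 = _check_points(p2[0], p2[1])
    phi1, phi2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = phi2 - phi1
    dlmb = np.deg2rad(lon2 - lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlmb / 2.0) ** 2
    return earth_radius_km * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def route_distance(points, earth_radius_km: float = EARTH_RADIUS_KM) -> float:
    """Sum of consecutive-leg great-circle distances along an ordered route.

    `points` is a sequence of (lat, lon) pairs or an (n, 2) array.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("route needs >= 2 (lat, lon) points")
    legs = haversine(
        (pts[:-1, 0], pts[:-1, 1]), (pts[1:, 0], pts[1:, 1]), earth_radius_km
    )
    return float(np.sum(legs))


def detour_index(points, origin=None, destination=None,
                 earth_radius_km: float = EARTH_RADIUS_KM) -> float | None:
    """Route length divided by the direct origin-destination distance.

    Defaults origin/destination to the route's first/last points. Returns
    None (undefined) when origin and destination coincide.
    """
    pts = np.asarray(points, dtype=float)
    origin = pts[0] if origin is None else np.asarray(origin, dtype=float)
    destination = pts[-1] if destination is None else np.asarray(destination, dtype=float)
    direct = float(haversine((origin[0], origin[1]), (destination[0], destination[1]),
                             earth_radius_km))
    if direct == 0.0:
        return None
    return route_distance(pts, earth_radius_km) / direct


def summarize_route(points, earth_radius_km: float = EARTH_RADIUS_KM) -> RouteSummary:
    pts = np.asarray(points, dtype=float)
    direct = float(haversine((pts[0, 0], pts[0, 1]), (pts[-1, 0], pts[-1, 1]),
                             earth_radius_km))
    total = route_distance(pts, earth_radius_km)
    return RouteSummary(
        endpoint_distance_km=direct,
        route_distance_km=total,
        detour_index=(total / direct) if direct > 0 else None,
    )


def route_summary_frame(summary: RouteSummary) -> pd.DataFrame:
    """One-row CSV-ready frame with unit-suffixed columns."""
    return pd.DataFrame(
        {
            "endpoint_distance_km": [summary.endpoint_distance_km],
            "route_distance_km": [summary.route_distance_km],
            "detour_index": [summary.detour_index],
        }
    )
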