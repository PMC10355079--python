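"""NOAA solar-position computations.

Implements the NOAA Solar Calculator algorithm (low-precision ephemeris,
documented accuracy better than 0.1 deg for years 1990-2030) on vectorized
UTC timestamps.  All angles are in degrees, longitudes east-positive.

No atmospheric refraction correction is applied: threshold light-level
geolocation calibrates an *effective* sun elevation angle that absorbs
refraction, and the synthetic light generator and the position solver must
share the same geometric model for round-trips to be exact.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "julian_century",
    "solar_declination",
    "equation_of_time",
    "solar_elevation",
    "solar_noon_longitude",
]

_J2000 = 2451545.0


def _to_utc_seconds(times) -> np.ndarray:
    """Convert datetime-like input to float seconds since the Unix epoch (UTC)."""
    t = pd.to_datetime(times, utc=True)
    if isinstance(t, pd.Timestamp):
        return np.asarray(t.value / 1e9)
    return pd.DatetimeIndex(t).asi8 / 1e9


def julian_century(times) -> np.ndarray:
    """Julian centuries since J2000.0 for UTC datetime-like input."""
    jd = _to_utc_seconds(times) / 86400.0 + 2440587.5
    return (jd - _J2000) / 36525.0


def _sun_geometry(jc: np.ndarray):
    """Declination (deg) and equation of time (minutes) at Julian century jc."""
    gmls = np.mod(280.46646 + jc * (36000.76983 + jc * 0.0003032), 360.0)
    gmas = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    rad = np.deg2rad
    eqctr = (
        np.sin(rad(gmas)) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + np.sin(rad(2 * gmas)) * (0.019993 - 0.000101 * jc)
        + np.sin(rad(3 * gmas)) * 0.000289
    )
    true_long = gmls + eqctr
    app_long = true_long - 0.00569 - 0.00478 * np.sin(rad(125.04 - 1934.136 * jc))
    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * np.cos(rad(125.04 - 1934.136 * jc))
    declination = np.rad2deg(np.arcsin(np.sin(rad(obliq)) * np.sin(rad(app_long))))
    vary = np.tan(rad(obliq / 2.0)) ** 2
    eot = 4.0 * np.rad2deg(
        vary * np.sin(2 * rad(gmls))
        - 2.0 * ecc * np.sin(rad(gmas))
        + 4.0 * ecc * vary * np.sin(rad(gmas)) * np.cos(2 * rad(gmls))
        - 0.5 * vary**2 * np.sin(4 * rad(gmls))
        - 1.25 * ecc**2 * np.sin(2 * rad(gmas))
    )
    return declination, eot


def solar_declination(times) -> np.ndarray:
    """Apparent solar declination in degrees."""
    return _sun_geometry(julian_century(times))[0]


def equation_of_time(times) -> np.ndarray:
    """Equation of time in minutes (apparent minus mean solar time)."""
    return _sun_geometry(julian_century(times))[1]


def solar_elevation(times, lat, lon) -> np.ndarray:
    """Geometric solar elevation angle in degrees (no refraction).

    Parameters
    ----------
    times : datetime-like or array of datetimes (UTC)
    lat, lon : scalar or array, degrees (lon east-positive)
    """
    sec = _to_utc_seconds(times)
    jc = (sec / 86400.0 + 2440587.5 - _J2000) / 36525.0
    decl, eot = _sun_geometry(jc)
    utc_minutes = np.mod(sec, 86400.0) / 60.0
    tst = np.mod(utc_minutes + eot + 4.0 * np.asarray(lon, dtype=float), 1440.0)
    hour_angle = tst / 4.0 - 180.0
    rad = np.deg2rad
    sin_el = np.sin(rad(lat)) * np.sin(rad(decl)) + np.cos(rad(lat)) * np.cos(
        rad(decl)
    ) * np.cos(rad(hour_angle))
    return np.rad2deg(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def solar_noon_longitude(noon_time) -> np.ndarray:
    """Longitude (deg east) at which the sun culminates at `noon_time` UTC."""
    sec = _to_utc_seconds(noon_time)
    jc = (sec / 86400.0 + 2440587.5 - _J2000) / 36525.0
    _, eot = _sun_geometry(jc)
    utc_minutes = np.mod(sec, 86400.0) / 60.0
    lon = (720.0 - utc_minutes - eot) / 4.0
    return np.mod(lon + 180.0, 360.0) - 180.0
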