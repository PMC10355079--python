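"""Threshold light-level geolocation.

Twilight events are the times at which measured light crosses a fixed lux
threshold (5 lx for conventional geolocators, 2 lx for the multi-sensor
loggers).  Longitude follows from the midpoint of a rise/set pair (solar
noon); latitude is solved from day length through the hour-angle relation

    cos H = (sin a - sin phi sin delta) / (cos phi cos delta)

with a the calibrated sun elevation angle and delta the solar declination.
Near the equinoxes (delta -> 0) the equation loses latitude information and
estimates are flagged undefined.

The sun angle is either fixed at civil twilight (-6 deg) or estimated by
Hill-Ekstrom calibration: sweep candidate angles in 0.1 deg increments over
a known stationary period and keep the angle that stabilizes the latitude
series (minimum standard deviation, with a penalty for days on which no
latitude exists).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import solar

__all__ = [
    "CalibrationError",
    "CalibrationResult",
    "detect_twilights",
    "edit_twilights",
    "twilight_pairs",
    "solve_latitude",
    "position_from_twilight_pair",
    "positions_from_twilights",
    "hill_ekstrom_calibrate",
    "HillEkstromCalibrator",
    "stationary_periods",
]

CIVIL_TWILIGHT_ANGLE = -6.0
DEFAULT_ANGLE_GRID = np.round(np.arange(-9.0, -1.0 + 1e-9, 0.1), 1)


class CalibrationError(RuntimeError):
    """Raised when no swept sun angle yields any defined latitude."""


# ---------------------------------------------------------------- twilights

def detect_twilights(light: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Detect threshold crossings in a regularly sampled light series.

    Crossing times are linearly interpolated between the two samples
    straddling the threshold (midpoint for binary above/below series).
    Returns a frame with columns ``time``, ``kind`` ('rise'/'set') and
    ``edited`` (False).  Days without any crossing simply contribute no
    events (polar-type days).
    """
    t = pd.to_datetime(light["timestamp_utc"]).to_numpy()
    if "lux" in light.columns:
        val = light["lux"].to_numpy(dtype=float)
        above = val > threshold
    else:
        above = light["above"].to_numpy(dtype=bool)
        val = above.astype(float)
        threshold = 0.5
    if (val < 0).any():
        raise ValueError("negative light values")
    change = np.flatnonzero(above[1:] != above[:-1])
    times, kinds = [], []
    for i in change:
        l0, l1 = val[i], val[i + 1]
        frac = 0.5 if l1 == l0 else (threshold - l0) / (l1 - l0)
        frac = min(max(frac, 0.0), 1.0)
        times.append(pd.Timestamp(t[i]) + frac * (pd.Timestamp(t[i + 1]) - pd.Timestamp(t[i])))
        kinds.append("rise" if above[i + 1] else "set")
    return pd.DataFrame({"time": times, "kind": kinds, "edited": False})


def edit_twilights(
    events: pd.DataFrame, window_days: int = 4, max_dev_min: float = 45.0
) -> pd.DataFrame:
    """Correct or remove twilight events inconsistent with neighboring days.

    An event whose time-of-day deviates more than ``max_dev_min`` minutes
    from the median of same-kind events within +/- ``window_days`` is moved
    to that median (``edited`` set); events with fewer than two neighbors in
    the window are dropped as isolated.
    """
    if events.empty:
        return events.copy()
    ev = events.sort_values("time").reset_index(drop=True).copy()
    tod = (ev["time"].dt.hour * 60 + ev["time"].dt.minute + ev["time"].dt.second / 60).to_numpy()
    day = ev["time"].dt.normalize().to_numpy()
    keep = np.ones(len(ev), dtype=bool)
    new_time = ev["time"].copy()
    edited = ev["edited"].to_numpy().copy()
    for k in ("rise", "set"):
        sel = np.flatnonzero((ev["kind"] == k).to_numpy())
        for i in sel:
            near = sel[
                (np.abs((day[sel] - day[i]) / np.timedelta64(1, "D")) <= window_days) & (sel != i)
            ]
            if len(near) < 2:
                keep[i] = False
                continue
            # wrapped minute offsets of neighbors relative to this event
            d = (tod[near] - tod[i] + 720.0) % 1440.0 - 720.0
            med = float(np.median(d))
            if abs(med) > max_dev_min:
                new_time.iloc[i] = ev["time"].iloc[i] + pd.Timedelta(minutes=med)
                edited[i] = True
    out = ev.loc[keep].copy()
    out["time"] = new_time[keep]
    out["edited"] = edited[keep]
    return out.sort_values("time").reset_index(drop=True)


def twilight_pairs(events: pd.DataFrame) -> pd.DataFrame:
    """Pair each rise with the next set within 24 h -> one row per day."""
    ev = events.sort_values("time").reset_index(drop=True)
    rows = []
    for i in range(len(ev) - 1):
        if ev["kind"].iloc[i] == "rise" and ev["kind"].iloc[i + 1] == "set":
            rise, tset = ev["time"].iloc[i], ev["time"].iloc[i + 1]
            if pd.Timedelta(0) < tset - rise < pd.Timedelta(hours=24):
                rows.append({"date": rise.normalize(), "rise_utc": rise, "set_utc": tset})
    return pd.DataFrame(rows, columns=["date", "rise_utc", "set_utc"])


# ---------------------------------------------------------------- positions

def solve_latitude(half_day_deg, declination_deg, sun_angle: float):
    """Latitude(s) in degrees satisfying the day-length equation, NaN when
    undefined.

    Solves sin(a) = sin(phi) sin(delta) + cos(phi) cos(delta) cos(H) for phi
    given the half-day hour angle H (degrees), analytically via the
    harmonic-addition identity; when both solution branches are physical the
    one closer to the equator is returned.
    """
    H = np.deg2rad(np.asarray(half_day_deg, dtype=float))
    delta = np.deg2rad(np.asarray(declination_deg, dtype=float))
    A = np.sin(delta)
    B = np.cos(delta) * np.cos(H)
    R = np.hypot(A, B)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.sin(np.deg2rad(sun_angle)) / R
    psi = np.arctan2(B, A)
    base = np.arcsin(np.clip(s, -1.0, 1.0))
    cand = np.stack([base - psi, np.pi - base - psi])
    cand = (cand + np.pi) % (2 * np.pi) - np.pi
    lat = np.rad2deg(cand)
    ok = (np.abs(s) <= 1.0) & (np.abs(lat) <= 89.5)
    lat = np.where(ok, lat, np.nan)
    # prefer the branch nearer the equator when both are physical
    pick = np.where(
        np.isnan(lat[0]) | (~np.isnan(lat[1]) & (np.abs(lat[1]) < np.abs(lat[0]))),
        lat[1],
        lat[0],
    )
    return pick


def position_from_twilight_pair(rise, tset, sun_angle: float) -> dict:
    """Daily position from one rise/set pair.

    Longitude comes from the solar-noon midpoint; latitude from day length
    (NaN with ``lat_defined=False`` when the equation has no solution, e.g.
    near the equinoxes).
    """
    rise, tset = pd.Timestamp(rise), pd.Timestamp(tset)
    if tset <= rise:
        raise ValueError("set must follow rise")
    noon = rise + (tset - rise) / 2
    lon = float(solar.solar_noon_longitude(noon))
    half_day_deg = 15.0 * (tset - rise) / pd.Timedelta(hours=2)
    decl = float(solar.solar_declination(noon))
    lat = float(solve_latitude(half_day_deg, decl, sun_angle))
    return {
        "date": rise.normalize(),
        "lat_deg": lat,
        "lon_deg": lon,
        "lat_defined": not np.isnan(lat),
    }


def positions_from_twilights(events: pd.DataFrame, sun_angle: float = CIVIL_TWILIGHT_ANGLE) -> pd.DataFrame:
    """Daily position estimates from an edited twilight series."""
    pairs = twilight_pairs(events)
    rows = [
        position_from_twilight_pair(r.rise_utc, r.set_utc, sun_angle)
        for r in pairs.itertuples()
    ]
    return pd.DataFrame(rows, columns=["date", "lat_deg", "lon_deg", "lat_defined"])


# ------------------------------------------------------------- calibration

@dataclass(frozen=True)
class CalibrationResult:
    sun_angle: float
    objective_curve: pd.DataFrame  # angle_deg, sd_lat_deg, n_undefined, objective
    curvature: float               # quadratic trend of latitude vs time at the optimum


def _latitude_curvature(days: np.ndarray, lats: np.ndarray) -> float:
    ok = ~np.isnan(lats)
    if ok.sum() < 3:
        return np.nan
    x = days[ok] - days[ok].mean()
    return float(np.polyfit(x, lats[ok], 2)[0])


def hill_ekstrom_calibrate(
    events: pd.DataFrame,
    stationary_window: tuple | None = None,
    angle_grid=DEFAULT_ANGLE_GRID,
    lambda_undefined: float = 1.0,
) -> CalibrationResult:
    """Hill-Ekstrom sun-angle calibration over a known stationary period.

    For each candidate angle the daily latitudes of the (windowed) twilight
    series are computed; the objective is the standard deviation of the
    defined latitudes plus ``lambda_undefined`` degrees per undefined day.
    The angle minimizing the objective is returned together with the full
    curve and a concave/convex trend diagnostic at the optimum.
    """
    pairs = twilight_pairs(events)
    if stationary_window is not None:
        lo, hi = map(pd.Timestamp, stationary_window)
        pairs = pairs[(pairs["date"] >= lo) & (pairs["date"] <= hi)]
    if len(pairs) < 5:
        raise CalibrationError("too few twilight pairs in the stationary window")
    # a plausible light series yields one rise/set pair per day; a series
    # dominated by spurious crossings carries no day-length information
    if len(pairs) > 2 * pairs["date"].nunique():
        raise CalibrationError(
            "implausible twilight structure: more than two rise/set pairs "
            "per day on average; clean the light series before calibrating"
        )
    noon = pairs["rise_utc"] + (pairs["set_utc"] - pairs["rise_utc"]) / 2
    half_day = (15.0 * (pairs["set_utc"] - pairs["rise_utc"]) / pd.Timedelta(hours=2)).to_numpy()
    decl = solar.solar_declination(noon)
    days = (pairs["date"] - pairs["date"].iloc[0]) / pd.Timedelta(days=1)
    days = days.to_numpy(dtype=float)

    rows = []
    best = None
    angle_grid = np.asarray(angle_grid, dtype=float)
    for a in angle_grid:
        lats = solve_latitude(half_day, decl, a)
        n_undef = int(np.isnan(lats).sum())
        n_def = len(lats) - n_undef
        sd = float(np.std(lats[~np.isnan(lats)], ddof=1)) if n_def >= 2 else np.nan
        objective = (sd if n_def >= 2 else np.inf) + lambda_undefined * n_undef
        rows.append({"angle_deg": a, "sd_lat_deg": sd, "n_undefined": n_undef,
                     "objective": objective})
        if np.isfinite(objective) and (best is None or objective < best[1]):
            best = (a, objective, lats)
    curve = pd.DataFrame(rows)
    if best is None:
        raise CalibrationError("no swept angle produced defined latitudes")
    return CalibrationResult(
        sun_angle=float(best[0]),
        objective_curve=curve,
        curvature=_latitude_curvature(days, best[2]),
    )


class HillEkstromCalibrator(BaseEstimator):
    """Sklearn-style estimator: fit a sun elevation angle from a light series
    recorded at a stationary site, then predict daily positions.

    Parameters
    ----------
    threshold : lux threshold defining twilight (2 lx for MDLs, 5 lx for
        conventional geolocators).
    angle_min, angle_max, angle_step : swept sun-angle grid in degrees
        (0.1 deg increments by default).
    lambda_undefined : penalty (degrees per day) for days without a defined
        latitude in the calibration objective.
    edit_window_days, edit_max_dev_min : twilight-editing parameters.

    Attributes (after ``fit``)
    --------------------------
    sun_angle_ : selected sun elevation angle (degrees, negative below horizon)
    objective_curve_ : the full angle -> objective curve
    curvature_ : latitude-vs-time quadratic trend diagnostic at the optimum
    """

    def __init__(
        self,
        threshold: float = 2.0,
        angle_min: float = -9.0,
        angle_max: float = -1.0,
        angle_step: float = 0.1,
        lambda_undefined: float = 1.0,
        edit_window_days: int = 4,
        edit_max_dev_min: float = 45.0,
    ):
        self.threshold = threshold
        self.angle_min = angle_min
        self.angle_max = angle_max
        self.angle_step = angle_step
        self.lambda_undefined = lambda_undefined
        self.edit_window_days = edit_window_days
        self.edit_max_dev_min = edit_max_dev_min

    def _events(self, light: pd.DataFrame) -> pd.DataFrame:
        ev = detect_twilights(light, self.threshold)
        return edit_twilights(ev, self.edit_window_days, self.edit_max_dev_min)

    def fit(self, X: pd.DataFrame, y=None, stationary_window=None):
        grid = np.round(
            np.arange(self.angle_min, self.angle_max + 1e-9, self.angle_step),
            6,
        )
        res = hill_ekstrom_calibrate(
            self._events(X), stationary_window, grid, self.lambda_undefined
        )
        self.sun_angle_ = res.sun_angle
        self.objective_curve_ = res.objective_curve
        self.curvature_ = res.curvature
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Daily positions for a light series using the fitted sun angle."""
        if not hasattr(self, "sun_angle_"):
            raise RuntimeError("calibrator is not fitted")
        return positions_from_twilights(self._events(X), self.sun_angle_)


# ------------------------------------------------------ stationary periods

def _binary_segments(x: np.ndarray, min_len: int, min_shift: float):
    """Recursive binary segmentation on mean shifts of a 1-D series."""
    cum = np.concatenate([[0.0], np.cumsum(x)])
    cum2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(i, j):  # [i, j)
        n = j - i
        s = cum[j] - cum[i]
        return (cum2[j] - cum2[i]) - s * s / n

    # a split is kept when it removes at least min_shift^2 of SSE -- the
    # reduction produced by a mean shift of min_shift lasting >= ~1-2 days
    penalty = min_shift**2

    def split(i, j, out):
        n = j - i
        if n < 2 * min_len:
            out.append((i, j))
            return
        ks = np.arange(i + min_len, j - min_len + 1)
        costs = np.array([sse(i, k) + sse(k, j) for k in ks])
        k = int(ks[np.argmin(costs)])
        if sse(i, j) - costs.min() < penalty:
            out.append((i, j))
            return
        split(i, k, out)
        split(k, j, out)

    out: list[tuple[int, int]] = []
    split(0, len(x), out)
    return sorted(out)


def stationary_periods(
    positions: pd.DataFrame,
    min_days: int = 3,
    min_shift_deg: float = 1.0,
) -> pd.DataFrame:
    """Segment daily positions into stationary periods of >= ``min_days``.

    A change-point segmentation on the longitude series (binary segmentation
    on mean shifts, minimum segment length 2 days, accepted when the means
    differ by >= ``min_shift_deg``) replaces visual inspection of longitude
    plots; segments shorter than ``min_days`` are then discarded.  Latitude
    statistics use defined latitudes only.
    """
    pos = positions.sort_values("date").reset_index(drop=True)
    if pos.empty:
        return pd.DataFrame(
            columns=["start", "end", "n_days", "mean_lat_deg", "mean_lon_deg",
                     "sd_lat_deg", "sd_lon_deg"]
        )
    lon = pos["lon_deg"].to_numpy(dtype=float)
    segs = _binary_segments(lon, min_len=2, min_shift=min_shift_deg)
    rows = []
    for i, j in segs:
        if j - i < min_days:
            continue
        chunk = pos.iloc[i:j]
        lats = chunk["lat_deg"].to_numpy(dtype=float)
        lats = lats[~np.isnan(lats)]
        rows.append(
            {
                "start": chunk["date"].iloc[0],
                "end": chunk["date"].iloc[-1],
                "n_days": j - i,
                "mean_lat_deg": float(np.mean(lats)) if len(lats) else np.nan,
                "mean_lon_deg": float(chunk["lon_deg"].mean()),
                "sd_lat_deg": float(np.std(lats, ddof=1)) if len(lats) > 1 else np.nan,
                "sd_lon_deg": float(chunk["lon_deg"].std(ddof=1)),
            }
        )
    return pd.DataFrame(rows, columns=["start", "end", "n_days", "mean_lat_deg",
                                       "mean_lon_deg", "sd_lat_deg", "sd_lon_deg"])
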