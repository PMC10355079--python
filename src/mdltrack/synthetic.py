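"""Ground-truthed synthetic multi-sensor data-logger (MDL) streams.

Emulates the sampling scheme of a shorebird activity/light logger: every
5 minutes the accelerometer takes 5 binary subsamples whose sum is an
activity score 0-5 (12 scores per clock hour), and the light sensor records
lux values whose threshold crossings follow solar geometry at the animal's
true position.  Itineraries plant flights along great-circle legs at a
configurable airspeed (default 16 m/s, as recorded for common ringed
plovers), so every downstream stage can be validated against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import haversine
from .solar import solar_elevation

__all__ = [
    "BREEDING_SITE_LATLON",
    "MDL_LIGHT_WINDOWS",
    "Site",
    "ItinerarySpec",
    "GeneratorNoise",
    "make_itinerary",
    "planted_flights",
    "true_position",
    "simulate_activity",
    "simulate_light",
    "in_mdl_light_windows",
]

#: Breeding-site coordinates used as the default itinerary origin
#: (Ottenby, southeast Sweden; 56 deg 13' 58" N, 16 deg 24' 40" E).
BREEDING_SITE_LATLON = (56.2328, 16.4111)

#: Month-day windows in which the logger samples light
#: (1-20 Aug, 1-10 Dec, 1-10 Feb, 21 Feb - 3 Mar).
MDL_LIGHT_WINDOWS = (((8, 1), (8, 20)), ((12, 1), (12, 10)),
                     ((2, 1), (2, 10)), ((2, 21), (3, 3)))

SLOT = pd.Timedelta(minutes=5)
DEFAULT_AIRSPEED_MS = 16.0


@dataclass(frozen=True)
class Site:
    """A stationary occupancy: position plus arrival/departure (UTC)."""

    lat: float
    lon: float
    arrival: pd.Timestamp
    departure: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "arrival", pd.Timestamp(self.arrival))
        object.__setattr__(self, "departure", pd.Timestamp(self.departure))
        if not (-90.0 <= self.lat <= 90.0 and -180.0 <= self.lon <= 180.0):
            raise ValueError("site coordinates out of bounds")
        if self.arrival >= self.departure:
            raise ValueError("site arrival must precede departure")


@dataclass(frozen=True)
class GeneratorNoise:
    """Logger imperfection knobs; all probabilities per 5-min record/sample."""

    p_active_rest: float = 0.0
    p_inactive_flight: float = 0.0
    p_missing_record: float = 0.0
    p_shading: float = 0.0

    def __post_init__(self):
        for name in ("p_active_rest", "p_inactive_flight", "p_missing_record", "p_shading"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class ItinerarySpec:
    """Ordered sites with the planted flights that connect them.

    ``flights`` holds (origin site index, start UTC, duration hours); flight
    starts are aligned to the 5-min sampling grid and durations are whole
    numbers of 5-min slots so that planted truth lives on the logger's grid.
    """

    sites: tuple[Site, ...]
    flights: tuple[tuple[int, pd.Timestamp, float], ...]
    airspeed_ms: float = DEFAULT_AIRSPEED_MS
    seed: int = 0

    def __post_init__(self):
        for a, b in zip(self.sites, self.sites[1:]):
            if a.departure > b.arrival:
                raise ValueError("sites must be chronologically ordered")
        prev_end = None
        for i, start, dur in self.flights:
            start = pd.Timestamp(start)
            end = start + pd.Timedelta(hours=dur)
            if prev_end is not None and start < prev_end:
                raise ValueError("flights overlap")
            prev_end = end


def _unit_vec(lat, lon):
    phi, lmb = np.deg2rad(lat), np.deg2rad(lon)
    return np.stack([np.cos(phi) * np.cos(lmb), np.cos(phi) * np.sin(lmb), np.sin(phi)], axis=-1)


def _latlon(vec):
    x, y, z = vec[..., 0], vec[..., 1], vec[..., 2]
    return np.rad2deg(np.arcsin(np.clip(z, -1, 1))), np.rad2deg(np.arctan2(y, x))


def gc_interpolate(p1, p2, frac):
    """Points at fraction(s) `frac` along the great circle from p1 to p2."""
    v1, v2 = _unit_vec(*p1), _unit_vec(*p2)
    omega = np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))
    if omega < 1e-12:
        f = np.asarray(frac)
        return np.broadcast_to(p1[0], f.shape).copy(), np.broadcast_to(p1[1], f.shape).copy()
    f = np.asarray(frac)[..., None]
    v = (np.sin((1 - f) * omega) * v1 + np.sin(f * omega) * v2) / np.sin(omega)
    return _latlon(v)


def _snap_slots(ts: pd.Timestamp) -> pd.Timestamp:
    return ts.floor("5min")


def make_itinerary(
    origin: Site,
    destination: Site,
    n_stopovers: int = 3,
    season: str = "autumn",
    seed: int = 0,
    airspeed_ms: float = DEFAULT_AIRSPEED_MS,
    jitter: float = 0.05,
    stopover_median_d: float = 1.1,
    stopover_sigma: float = 0.5,
) -> ItinerarySpec:
    """Plant an itinerary of `n_stopovers` stopovers on the origin->destination
    great circle.

    Stopovers are placed at even along-track fractions with lognormal jitter
    of relative scale `jitter`; stopover durations are lognormal with the
    given median (days).  Flight durations equal leg distance / airspeed,
    rounded to the 5-min sampling grid.  Deterministic for a fixed seed.
    """
    if n_stopovers < 0:
        raise ValueError("n_stopovers must be >= 0")
    if (origin.lat, origin.lon) == (destination.lat, destination.lon):
        raise ValueError("origin and destination coincide")
    sep_km = float(haversine((origin.lat, origin.lon), (destination.lat, destination.lon)))
    if sep_km > np.pi * 6371.0 * (1 - 1e-4):
        raise ValueError("antipodal endpoints: great circle is ambiguous")
    if season not in ("autumn", "spring"):
        raise ValueError("season must be 'autumn' or 'spring'")

    rng = np.random.default_rng(seed)
    fracs = (np.arange(1, n_stopovers + 1) / (n_stopovers + 1))
    if n_stopovers:
        fracs = np.clip(fracs + rng.normal(0.0, jitter / (n_stopovers + 1), n_stopovers), 0.02, 0.98)
        fracs.sort()
    lats, lons = gc_interpolate((origin.lat, origin.lon), (destination.lat, destination.lon), fracs)

    kmh = airspeed_ms * 3.6
    waypoints = [(origin.lat, origin.lon)] + list(zip(np.atleast_1d(lats), np.atleast_1d(lons))) + [
        (destination.lat, destination.lon)
    ]
    sites: list[Site] = []
    flights: list[tuple[int, pd.Timestamp, float]] = []
    t = _snap_slots(origin.departure)
    sites.append(Site(origin.lat, origin.lon, origin.arrival, t))
    for i in range(len(waypoints) - 1):
        leg_km = float(haversine(waypoints[i], waypoints[i + 1]))
        n_slots = max(1, int(round(leg_km / kmh * 12)))
        dur_h = n_slots / 12.0
        flights.append((i, t, dur_h))
        arrive = t + n_slots * SLOT
        if i + 1 < len(waypoints) - 1:
            stay_d = float(np.exp(np.log(stopover_median_d) + stopover_sigma * rng.standard_normal()))
            depart = _snap_slots(arrive + pd.Timedelta(days=max(stay_d, 0.25)))
            lat, lon = waypoints[i + 1]
            sites.append(Site(float(lat), float(lon), arrive, depart))
            t = depart
        else:
            depart = max(pd.Timestamp(destination.departure), arrive + pd.Timedelta(days=30))
            sites.append(Site(destination.lat, destination.lon, arrive, depart))
    return ItinerarySpec(tuple(sites), tuple(flights), airspeed_ms, seed)


def planted_flights(itin: ItinerarySpec) -> pd.DataFrame:
    """Ground-truth flight intervals as a DataFrame (start/end UTC, duration_h)."""
    rows = [
        {
            "start_utc": pd.Timestamp(start),
            "end_utc": pd.Timestamp(start) + pd.Timedelta(hours=dur),
            "duration_h": dur,
        }
        for _, start, dur in itin.flights
    ]
    return pd.DataFrame(rows, columns=["start_utc", "end_utc", "duration_h"])


def true_position(itin: ItinerarySpec, times) -> pd.DataFrame:
    """True (lat, lon) of the animal at each time.

    At a site between arrival and departure the position is the site's;
    during a flight it is interpolated along the great-circle leg at constant
    ground speed.  Before the first site / after the last, the edge site's
    position is used.
    """
    t = pd.DatetimeIndex(pd.to_datetime(times))
    lat = np.empty(len(t))
    lon = np.empty(len(t))
    lat.fill(np.nan)
    lon.fill(np.nan)
    sec = t.asi8 / 1e9

    for s in itin.sites:
        m = (sec >= s.arrival.value / 1e9) & (sec <= s.departure.value / 1e9)
        lat[m], lon[m] = s.lat, s.lon
    for i, start, dur in itin.flights:
        t0 = pd.Timestamp(start).value / 1e9
        t1 = t0 + dur * 3600.0
        m = (sec > t0) & (sec < t1)
        if m.any():
            frac = (sec[m] - t0) / (t1 - t0)
            p1 = (itin.sites[i].lat, itin.sites[i].lon)
            p2 = (itin.sites[i + 1].lat, itin.sites[i + 1].lon)
            lat[m], lon[m] = gc_interpolate(p1, p2, frac)
    lat[sec < itin.sites[0].arrival.value / 1e9] = itin.sites[0].lat
    lon[sec < itin.sites[0].arrival.value / 1e9] = itin.sites[0].lon
    lat[sec > itin.sites[-1].departure.value / 1e9] = itin.sites[-1].lat
    lon[sec > itin.sites[-1].departure.value / 1e9] = itin.sites[-1].lon
    return pd.DataFrame({"timestamp_utc": t, "lat_deg": lat, "lon_deg": lon})


def _flight_mask(itin: ItinerarySpec, slot_starts: pd.DatetimeIndex) -> np.ndarray:
    sec = slot_starts.asi8 / 1e9
    mask = np.zeros(len(slot_starts), dtype=bool)
    for _, start, dur in itin.flights:
        t0 = pd.Timestamp(start).value / 1e9
        mask |= (sec >= t0) & (sec < t0 + dur * 3600.0)
    return mask


def simulate_activity(
    itin: ItinerarySpec,
    noise: GeneratorNoise = GeneratorNoise(),
    start=None,
    end=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the 5-min activity-score stream over [start, end).

    Each record is the sum of 5 Bernoulli subsamples: active with
    probability 1 - p_inactive_flight inside planted flights, p_active_rest
    outside.  Records are dropped independently with p_missing_record.
    Randomness is drawn per slot from counter-based streams so that the
    draws for a slot do not depend on which other records are kept.
    """
    start = pd.Timestamp(start) if start is not None else itin.sites[0].arrival
    end = pd.Timestamp(end) if end is not None else itin.sites[-1].departure
    if start >= end:
        raise ValueError("start must precede end")
    start = start.ceil("5min")
    slots = pd.date_range(start, end, freq="5min", inclusive="left")
    for _, fstart, dur in itin.flights:
        if pd.Timestamp(fstart) < start or pd.Timestamp(fstart) + pd.Timedelta(hours=dur) > end:
            raise ValueError("itinerary flights must lie within [start, end)")

    seed = itin.seed if seed is None else seed
    ss_sub, ss_miss = np.random.SeedSequence(seed).spawn(2)
    u_sub = np.random.default_rng(np.random.Philox(key=ss_sub.generate_state(1)[0])).random(
        (len(slots), 5)
    )
    u_miss = np.random.default_rng(np.random.Philox(key=ss_miss.generate_state(1)[0])).random(
        len(slots)
    )
    inflight = _flight_mask(itin, slots)
    p_active = np.where(inflight, 1.0 - noise.p_inactive_flight, noise.p_active_rest)
    scores = (u_sub < p_active[:, None]).sum(axis=1).astype(int)
    keep = u_miss >= noise.p_missing_record
    return pd.DataFrame(
        {
            "timestamp_utc": slots[keep],
            "score": scores[keep],
            "n_subsamples": 5,
        }
    )


def in_mdl_light_windows(times) -> np.ndarray:
    """Boolean mask: timestamps inside the logger's light-sampling windows."""
    t = pd.DatetimeIndex(pd.to_datetime(times))
    md = t.month * 100 + t.day
    mask = np.zeros(len(t), dtype=bool)
    for (m0, d0), (m1, d1) in MDL_LIGHT_WINDOWS:
        mask |= (md >= m0 * 100 + d0) & (md <= m1 * 100 + d1)
    return mask


def simulate_light(
    itin: ItinerarySpec,
    sun_angle: float = -6.0,
    threshold: float = 2.0,
    sample_interval_min: int = 5,
    p_shading: float = 0.0,
    start=None,
    end=None,
    restrict_to_windows: bool = False,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the light (lux) stream at the animal's true position.

    Lux is a monotone piecewise-linear map of solar elevation that crosses
    `threshold` exactly when the elevation crosses `sun_angle`, so that
    threshold geolocation can be validated as an exact round-trip.  Shaded
    samples (probability `p_shading`) are forced to 0 lux.
    """
    if not -18.0 <= sun_angle <= 6.0:
        raise ValueError("sun_angle must be in [-18, 6] degrees")
    if sample_interval_min < 1:
        raise ValueError("sample_interval_min must be >= 1")
    start = pd.Timestamp(start) if start is not None else itin.sites[0].arrival
    end = pd.Timestamp(end) if end is not None else itin.sites[-1].departure
    times = pd.date_range(start.ceil(f"{sample_interval_min}min"), end,
                          freq=f"{sample_interval_min}min", inclusive="left")
    if restrict_to_windows:
        times = times[in_mdl_light_windows(times)]
    pos = true_position(itin, times)
    elev = solar_elevation(times, pos["lat_deg"].to_numpy(), pos["lon_deg"].to_numpy())
    gain = max(threshold / 2.0, 0.5)  # lux per degree of elevation
    lux = np.maximum(threshold + gain * (elev - sun_angle), 0.0)
    if p_shading > 0.0:
        seed = itin.seed if seed is None else seed
        ss = np.random.SeedSequence(seed).spawn(3)[2]
        u = np.random.default_rng(np.random.Philox(key=ss.generate_state(1)[0])).random(len(times))
        lux[u < p_shading] = 0.0
    return pd.DataFrame({"timestamp_utc": times, "lux": lux})
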