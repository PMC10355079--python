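"""Flight/stopover segmentation from 5-min accelerometer activity scores.

The logger records an activity score 0-5 every 5 minutes (12 per hour).
Segmentation proceeds in three stages:

1.  Weighted hourly scores (0-60) are computed by summing the hour's twelve
    scores; hours >= a threshold (default 30) seed candidate flight hours,
    and maximal runs of such hours form clusters.
2.  Sub-threshold hours adjacent to a cluster are absorbed while they
    contain no zero scores; when zeros appear, the zeros of that hour and
    the following hour are summed and the bird is considered landed when
    the sum reaches >= 12 (i.e. >= 1 h of inactivity).  A single absorbable
    hour between two clusters merges them into one flight.
3.  Bout boundaries are refined to 5-min resolution: records scoring < 3
    are trimmed from the edges, and records scoring < 3 (or missing, which
    count as zeros) inside the bout are excluded from the flight duration.

Periods between flights become stopovers, or winter/breeding residency when
they fall outside the configured migration season windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SegmentationParams",
    "ActivitySegmenter",
    "weighted_hourly_scores",
    "find_flight_hour_clusters",
    "bridge_low_hours",
    "refine_bout",
    "segment",
    "summarize_track",
]

SLOT = pd.Timedelta(minutes=5)
HOUR = pd.Timedelta(hours=1)
RECORDS_PER_HOUR = 12

#: (start month-day, end month-day) windows treated as migration seasons
#: when labeling inter-flight gaps stopover vs residency.
DEFAULT_SEASON_WINDOWS = (((7, 15), (10, 15)), ((2, 1), (4, 30)))


@dataclass(frozen=True)
class SegmentationParams:
    high_hour_threshold: int = 30      # weighted score >= this marks a candidate flight hour
    record_flight_score: int = 3       # 5-min scores >= this count as flight
    landing_zero_sum: int = 12         # summed zeros over two hours that ends a flight
    weighting: str = "sum"             # "sum" or "scaled" (sum rescaled to 12 samples)

    def __post_init__(self):
        if not 0 < self.high_hour_threshold <= 60:
            raise ValueError("high_hour_threshold must be in (0, 60]")
        if not 0 < self.record_flight_score <= 5:
            raise ValueError("record_flight_score must be in (0, 5]")
        if self.weighting not in ("sum", "scaled"):
            raise ValueError("weighting must be 'sum' or 'scaled'")


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    if records.empty:
        return records.assign(timestamp_utc=pd.to_datetime(records.get("timestamp_utc", [])))
    rec = records.copy()
    rec["timestamp_utc"] = pd.to_datetime(rec["timestamp_utc"])
    if rec["timestamp_utc"].duplicated().any():
        raise ValueError("duplicate record timestamps")
    off_grid = (rec["timestamp_utc"].dt.minute % 5 != 0) | (rec["timestamp_utc"].dt.second != 0)
    if off_grid.any():
        raise ValueError("records must be aligned to the 5-min grid")
    if ((rec["score"] < 0) | (rec["score"] > 5)).any():
        raise ValueError("scores must be integers in 0..5")
    return rec.sort_values("timestamp_utc").reset_index(drop=True)


def weighted_hourly_scores(records: pd.DataFrame, params: SegmentationParams | None = None) -> pd.DataFrame:
    """Aggregate 5-min scores into weighted hourly scores (0-60).

    Returns a frame indexed by hour start with columns ``weighted_score``,
    ``n_records``, ``zero_count`` and ``any_zero``.  Absent records
    contribute 0 to the weighted score and count as zeros, consistent with
    the duration rule that treats failed subsampling as zeros.  Hours with
    no records at all are included (weighted 0) so that cluster adjacency is
    well defined.
    """
    params = params or SegmentationParams()
    rec = _validate_records(records)
    if rec.empty:
        return pd.DataFrame(
            columns=["weighted_score", "n_records", "zero_count", "any_zero"],
            index=pd.DatetimeIndex([], name="hour_start"),
        )
    hour = rec["timestamp_utc"].dt.floor("h")
    g = rec.groupby(hour)
    out = pd.DataFrame(
        {
            "weighted_score": g["score"].sum(),
            "n_records": g["score"].size(),
            "zero_count": g["score"].apply(lambda s: int((s == 0).sum())),
        }
    )
    full = pd.date_range(hour.min(), hour.max(), freq="h")
    out = out.reindex(full, fill_value=0)
    out.index.name = "hour_start"
    if params.weighting == "scaled":
        nz = out["n_records"].replace(0, RECORDS_PER_HOUR)
        out["weighted_score"] = (out["weighted_score"] * RECORDS_PER_HOUR / nz).round().astype(int)
    out["zero_count"] = out["zero_count"] + (RECORDS_PER_HOUR - out["n_records"]).clip(lower=0)
    out["any_zero"] = out["zero_count"] > 0
    return out


def find_flight_hour_clusters(hours: pd.DataFrame, params: SegmentationParams | None = None):
    """Maximal runs of consecutive hours with weighted score >= threshold.

    Returns a list of (first_hour, last_hour) inclusive timestamp pairs.
    """
    params = params or SegmentationParams()
    if hours.empty:
        return []
    high = hours["weighted_score"].to_numpy() >= params.high_hour_threshold
    idx = hours.index
    clusters = []
    i = 0
    while i < len(high):
        if high[i]:
            j = i
            while j + 1 < len(high) and high[j + 1]:
                j += 1
            clusters.append((idx[i], idx[j]))
            i = j + 1
        else:
            i += 1
    return clusters


def _zero_count(hours: pd.DataFrame, h: pd.Timestamp) -> int:
    # hours outside the summarized range have no records: all 12 count as zeros
    if h in hours.index:
        return int(hours.loc[h, "zero_count"])
    return RECORDS_PER_HOUR


def bridge_low_hours(clusters, hours: pd.DataFrame, params: SegmentationParams | None = None):
    """Absorb absorbable sub-threshold hours at cluster edges and merge
    clusters separated by a single absorbable hour.

    An hour is absorbed while it contains no zero scores; when it does, the
    zeros of that hour and the following hour (in the direction of travel
    away from the cluster) are summed — the flight ends if the sum reaches
    ``landing_zero_sum``, otherwise the hour is absorbed too.  The rule is
    applied symmetrically at bout starts.  Bridges never chain across gaps
    of more than one hour, so clusters further apart stay separate.
    """
    params = params or SegmentationParams()
    if not clusters:
        return []
    spans = [list(c) for c in clusters]

    # merge pass: single-hour gaps
    merged = [spans[0]]
    for nxt in spans[1:]:
        cur = merged[-1]
        gap_hours = int((nxt[0] - cur[1]) / HOUR) - 1
        if gap_hours == 1:
            gap = cur[1] + HOUR
            z = _zero_count(hours, gap)
            if z == 0 or z + _zero_count(hours, gap + HOUR) < params.landing_zero_sum:
                cur[1] = nxt[1]
                continue
        merged.append(nxt)

    def absorbable(h, following):
        z = _zero_count(hours, h)
        if z == 0:
            return True
        return z + _zero_count(hours, following) < params.landing_zero_sum

    # extension passes (bounded by neighboring clusters)
    out = []
    for k, span in enumerate(merged):
        lo_bound = merged[k - 1][1] if k > 0 else None
        hi_bound = merged[k + 1][0] if k + 1 < len(merged) else None
        h = span[1] + HOUR
        while (hi_bound is None or h < hi_bound) and h <= hours.index.max():
            if not absorbable(h, h + HOUR):
                break
            span[1] = h
            h += HOUR
        h = span[0] - HOUR
        while (lo_bound is None or h > lo_bound) and h >= hours.index.min():
            if not absorbable(h, h - HOUR):
                break
            span[0] = h
            h -= HOUR
        out.append((span[0], span[1]))
    return out


def refine_bout(span, records: pd.DataFrame, params: SegmentationParams | None = None,
                lo=None, hi=None):
    """Refine a cluster span to a flight bout at 5-min resolution.

    The span is first extended through records scoring >= the flight score
    that are contiguous with its edges (boundaries are defined *around* the
    cluster), then trimmed to the first/last such record.  Records scoring
    below the flight score, and missing slots, inside the bout are excluded
    from the flight duration but counted.  ``lo``/``hi`` bound the extension
    so neighboring bouts stay disjoint.

    Returns a dict (start/end UTC, duration_h, n_low_omitted,
    n_missing_as_zero) or None when the span holds no flight-score record.
    """
    params = params or SegmentationParams()
    rec = _validate_records(records)
    by_slot = rec.set_index("timestamp_utc")["score"]
    span_start, span_end = span[0], span[1] + HOUR  # half-open record window

    def score_at(t):
        return int(by_slot.get(t, -1))  # -1 = missing slot

    t = span_start - SLOT
    while (lo is None or t >= lo) and score_at(t) >= params.record_flight_score:
        span_start = t
        t -= SLOT
    t = span_end
    while (hi is None or t < hi) and score_at(t) >= params.record_flight_score:
        span_end = t + SLOT
        t += SLOT

    window = by_slot[(by_slot.index >= span_start) & (by_slot.index < span_end)]
    flight = window[window >= params.record_flight_score]
    if flight.empty:
        return None
    start = flight.index[0]
    end = flight.index[-1] + SLOT
    inside = window[(window.index >= start) & (window.index < end)]
    n_flight = int((inside >= params.record_flight_score).sum())
    n_low = int((inside < params.record_flight_score).sum())
    n_slots = int((end - start) / SLOT)
    return {
        "start_utc": start,
        "end_utc": end,
        "duration_h": n_flight / 12.0,
        "n_low_omitted": n_low,
        "n_missing_as_zero": n_slots - len(inside),
    }


def _in_season(t: pd.Timestamp, windows) -> bool:
    md = t.month * 100 + t.day
    return any(m0 * 100 + d0 <= md <= m1 * 100 + d1 for (m0, d0), (m1, d1) in windows)


def segment(
    records: pd.DataFrame,
    params: SegmentationParams | None = None,
    season_windows=DEFAULT_SEASON_WINDOWS,
):
    """Full segmentation: records -> (flight bouts, stopover/residency bouts).

    Flights and the gaps between them tile the analyzed interval.  A gap
    strictly between two flights that starts inside a migration season
    window is a stopover; all other gaps (including the leading and
    trailing periods) are residency.
    """
    params = params or SegmentationParams()
    rec = _validate_records(records)
    flight_cols = ["start_utc", "end_utc", "duration_h", "n_low_omitted", "n_missing_as_zero"]
    stop_cols = ["start_utc", "end_utc", "duration_d", "role"]
    if rec.empty:
        return pd.DataFrame(columns=flight_cols), pd.DataFrame(columns=stop_cols)

    hours = weighted_hourly_scores(rec, params)
    clusters = bridge_low_hours(find_flight_hour_clusters(hours, params), hours, params)
    bouts = []
    for k, c in enumerate(clusters):
        lo = clusters[k - 1][1] + HOUR if k > 0 else None
        hi = clusters[k + 1][0] if k + 1 < len(clusters) else None
        b = refine_bout(c, rec, params, lo=lo, hi=hi)
        if b is not None:
            bouts.append(b)
    flights = pd.DataFrame(bouts, columns=flight_cols)

    t0 = rec["timestamp_utc"].iloc[0]
    t1 = rec["timestamp_utc"].iloc[-1] + SLOT
    edges = [t0] + [t for b in bouts for t in (b["start_utc"], b["end_utc"])] + [t1]
    gaps = []
    for k in range(0, len(edges), 2):
        gs, ge = edges[k], edges[k + 1]
        if ge <= gs:
            continue
        interior = 0 < k < len(edges) - 2
        role = "stopover" if interior and _in_season(gs, season_windows) else "residency"
        gaps.append({
            "start_utc": gs,
            "end_utc": ge,
            "duration_d": (ge - gs) / pd.Timedelta(days=1),
            "role": role,
        })
    return flights, pd.DataFrame(gaps, columns=stop_cols)


def summarize_track(flights: pd.DataFrame, stopovers: pd.DataFrame) -> pd.Series:
    """Per-track summary statistics over segmented bouts.

    Medians are NaN when there are no bouts of the given kind; stopover
    statistics cover bouts with role 'stopover' only.
    """
    stops = stopovers[stopovers["role"] == "stopover"] if not stopovers.empty else stopovers
    return pd.Series(
        {
            "n_flights": len(flights),
            "n_stopovers": len(stops),
            "total_flight_h": float(flights["duration_h"].sum()) if len(flights) else 0.0,
            "total_stopover_d": float(stops["duration_d"].sum()) if len(stops) else 0.0,
            "median_flight_h": float(flights["duration_h"].median()) if len(flights) else np.nan,
            "median_stopover_d": float(stops["duration_d"].median()) if len(stops) else np.nan,
            "longest_flight_h": float(flights["duration_h"].max()) if len(flights) else 0.0,
        }
    )


class ActivitySegmenter(BaseEstimator):
    """Sklearn-style transformer turning activity records into bout tables.

    Parameters mirror :class:`SegmentationParams`; ``transform`` returns the
    flight-bout table, ``segment`` both bout tables.  The estimator is
    stateless (rule-based), so ``fit`` only validates input.
    """

    def __init__(
        self,
        high_hour_threshold: int = 30,
        record_flight_score: int = 3,
        landing_zero_sum: int = 12,
        weighting: str = "sum",
        season_windows=DEFAULT_SEASON_WINDOWS,
    ):
        self.high_hour_threshold = high_hour_threshold
        self.record_flight_score = record_flight_score
        self.landing_zero_sum = landing_zero_sum
        self.weighting = weighting
        self.season_windows = season_windows

    def _params(self) -> SegmentationParams:
        return SegmentationParams(
            self.high_hour_threshold,
            self.record_flight_score,
            self.landing_zero_sum,
            self.weighting,
        )

    def fit(self, X, y=None):
        _validate_records(X)
        self.n_records_ = len(X)
        return self

    def segment(self, X):
        return segment(X, self._params(), self.season_windows)

    def transform(self, X):
        flights, _ = self.segment(X)
        return flights

    def fit_transform(self, X, y=None):
        return self.fit(X).transform(X)
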