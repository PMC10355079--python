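"""Segmentation algorithm checks: hourly weighting, clustering, the landing
(zero-sum) rule, 5-min refinement and whole-track segmentation."""

import numpy as np
import pandas as pd
import pytest

from mdltrack import ActivitySegmenter, GeneratorNoise, simulate_activity
from mdltrack.activity import (
    SegmentationParams,
    bridge_low_hours,
    find_flight_hour_clusters,
    refine_bout,
    segment,
    summarize_track,
    weighted_hourly_scores,
)
from mdltrack.synthetic import ItinerarySpec, Site, planted_flights

from conftest import demo_itinerary, make_records

H = pd.Timedelta(hours=1)


def hours_from_scores(day0, hourly_scores):
    """Build records where each hour holds 12 equal 5-min scores... or a
    literal list per hour."""
    flat = []
    for h in hourly_scores:
        flat.extend([h] * 12 if np.isscalar(h) else h)
    return make_records(day0, flat)


class TestWeightedHourlyScores:
    def test_full_hour_of_max_scores_gives_60(self):
        hours = weighted_hourly_scores(make_records("2019-08-01 00:00", [5] * 12))
        assert hours["weighted_score"].iloc[0] == 60

    def test_all_zero_hour_gives_0(self):
        hours = weighted_hourly_scores(make_records("2019-08-01 00:00", [0] * 12))
        assert hours["weighted_score"].iloc[0] == 0

    def test_missing_records_count_as_zero(self):
        rec = make_records("2019-08-01 00:00", [5, None] * 6)
        hours = weighted_hourly_scores(rec)
        assert hours["weighted_score"].iloc[0] == 30
        assert hours["zero_count"].iloc[0] == 6
        assert hours["n_records"].iloc[0] == 6

    def test_duplicate_timestamps_rejected(self):
        rec = make_records("2019-08-01 00:00", [5] * 12)
        with pytest.raises(ValueError):
            weighted_hourly_scores(pd.concat([rec, rec.head(1)]))

    def test_scaled_weighting_rescales_incomplete_hours(self):
        rec = make_records("2019-08-01 00:00", [5, None] * 6)
        hours = weighted_hourly_scores(rec, SegmentationParams(weighting="scaled"))
        assert hours["weighted_score"].iloc[0] == 60


class TestClusters:
    def test_no_high_hours_no_clusters(self):
        hours = weighted_hourly_scores(hours_from_scores("2019-08-01", [1, 2, 2, 1]))
        assert find_flight_hour_clusters(hours) == []

    def test_single_run_detected(self):
        hours = weighted_hourly_scores(hours_from_scores("2019-08-01", [0, 5, 5, 0]))
        clusters = find_flight_hour_clusters(hours)
        assert clusters == [(pd.Timestamp("2019-08-01 01:00"), pd.Timestamp("2019-08-01 02:00"))]

    def test_threshold_monotonicity(self):
        # raising the threshold shrinks the set of flagged hours, so every
        # cluster at the higher threshold nests inside one at the lower
        # threshold and the total flagged hours never increase (the cluster
        # COUNT can rise when a run splits in two, so it is not asserted)
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 6, 24 * 12)
        hours = weighted_hourly_scores(make_records("2019-08-01", list(scores)))

        def clusters(t):
            return find_flight_hour_clusters(hours, SegmentationParams(high_hour_threshold=t))

        def total_hours(cl):
            return sum(int((b - a) / pd.Timedelta(hours=1)) + 1 for a, b in cl)

        thresholds = (10, 20, 30, 40, 50, 60)
        for lo_t, hi_t in zip(thresholds, thresholds[1:]):
            lo, hi = clusters(lo_t), clusters(hi_t)
            assert total_hours(hi) <= total_hours(lo)
            for a, b in hi:
                assert any(a0 <= a and b <= b0 for a0, b0 in lo)


class TestBridging:
    def test_zero_free_subthreshold_hour_absorbed(self):
        # hour of twelve 2s and 3s (weighted 28, no zeros) after a flight run
        hourly = [0, 5, 5, [2] * 8 + [3] * 4, 0, 0]
        rec = hours_from_scores("2019-08-01", hourly)
        hours = weighted_hourly_scores(rec)
        ext = bridge_low_hours(find_flight_hour_clusters(hours), hours)
        assert ext == [(pd.Timestamp("2019-08-01 01:00"), pd.Timestamp("2019-08-01 03:00"))]

    def test_landing_when_zero_sum_reaches_12(self):
        # adjacent hour with 6 zeros, following hour with 6 zeros -> landed
        hourly = [0, 5, 5, [4, 0] * 6, [1, 0] * 6, 0]
        rec = hours_from_scores("2019-08-01", hourly)
        hours = weighted_hourly_scores(rec)
        ext = bridge_low_hours(find_flight_hour_clusters(hours), hours)
        assert ext == [(pd.Timestamp("2019-08-01 01:00"), pd.Timestamp("2019-08-01 02:00"))]

    def test_clusters_merge_across_single_bridgeable_hour(self):
        # gap hour has 3 zeros; following (cluster) hour has none: sum 3 < 12
        gap = [3, 3, 3, 0] * 3  # weighted 27, 3 zeros
        hourly = [0, 5, 5, gap, 5, 5, 0]
        rec = hours_from_scores("2019-08-01", hourly)
        hours = weighted_hourly_scores(rec)
        ext = bridge_low_hours(find_flight_hour_clusters(hours), hours)
        assert ext == [(pd.Timestamp("2019-08-01 01:00"), pd.Timestamp("2019-08-01 05:00"))]

    def test_no_merge_across_two_subthreshold_hours(self):
        gap = [3, 3, 3, 0] * 3
        hourly = [0, 5, 5, gap, gap, 5, 5, 0]
        rec = hours_from_scores("2019-08-01", hourly)
        hours = weighted_hourly_scores(rec)
        ext = bridge_low_hours(find_flight_hour_clusters(hours), hours)
        assert len(ext) == 2


class TestRefine:
    def test_contiguous_block_duration(self):
        # 104 records >= 3 -> 8.67 h
        rec = make_records("2019-08-01 00:00", [0] * 12 + [4] * 104 + [0] * 12)
        hours = weighted_hourly_scores(rec)
        spans = bridge_low_hours(find_flight_hour_clusters(hours), hours)
        bout = refine_bout(spans[0], rec)
        assert bout["duration_h"] == pytest.approx(104 / 12)
        assert bout["start_utc"] == pd.Timestamp("2019-08-01 01:00")

    def test_exact_block_boundaries(self):
        rec = make_records("2019-08-01 00:00", [0, 0] + [4] * 100 + [0] * 10)
        hours = weighted_hourly_scores(rec)
        spans = bridge_low_hours(find_flight_hour_clusters(hours), hours)
        bout = refine_bout(spans[0], rec)
        assert bout["start_utc"] == pd.Timestamp("2019-08-01 00:10")
        assert bout["duration_h"] == pytest.approx(100 / 12)

    def test_interior_low_scores_omitted_from_duration(self):
        scores = [0] * 12 + [4] * 50 + [1, 1] + [4] * 50 + [0] * 12
        rec = make_records("2019-08-01 00:00", scores)
        hours = weighted_hourly_scores(rec)
        spans = bridge_low_hours(find_flight_hour_clusters(hours), hours)
        bout = refine_bout(spans[0], rec)
        assert bout["duration_h"] == pytest.approx(100 / 12)
        assert bout["n_low_omitted"] == 2
        # span unchanged: end still covers the full >=3 block
        assert bout["end_utc"] - bout["start_utc"] == 102 * pd.Timedelta(minutes=5)

    def test_cluster_without_flight_records_discarded(self):
        span = (pd.Timestamp("2019-08-01 01:00"), pd.Timestamp("2019-08-01 01:00"))
        rec = make_records("2019-08-01 01:00", [2] * 12)
        assert refine_bout(span, rec) is None

    def test_score_exactly_3_counts_as_flight(self):
        rec = make_records("2019-08-01 00:00", [0] * 12 + [3] * 104 + [0] * 12)
        hours = weighted_hourly_scores(rec)
        spans = bridge_low_hours(find_flight_hour_clusters(hours), hours)
        assert refine_bout(spans[0], rec)["duration_h"] == pytest.approx(104 / 12)


class TestSegment:
    def test_empty_input(self):
        flights, stops = segment(pd.DataFrame(columns=["timestamp_utc", "score"]))
        assert flights.empty and stops.empty

    def test_no_flights_single_residency(self):
        site = Site(56.0, 16.0, "2019-08-01", "2019-08-10")
        itin = ItinerarySpec((site,), (), seed=0)
        rec = simulate_activity(itin, GeneratorNoise(), "2019-08-01", "2019-08-05")
        flights, stops = segment(rec)
        assert flights.empty
        assert len(stops) == 1 and stops["role"].iloc[0] == "residency"

    def test_noiseless_recovery_equals_planted(self, itinerary, noiseless_activity):
        truth = planted_flights(itinerary)
        flights, stops = segment(noiseless_activity)
        assert len(flights) == len(truth)
        assert (flights["start_utc"].to_numpy() == truth["start_utc"].to_numpy()).all()
        assert (flights["end_utc"].to_numpy() == truth["end_utc"].to_numpy()).all()
        assert np.allclose(flights["duration_h"], truth["duration_h"])
        # 3 stopovers between 4 flights; leading/trailing residency
        assert (stops["role"] == "stopover").sum() == 3
        assert (stops["role"] == "residency").sum() == 2

    def test_partition_tiles_interval_without_overlap(self, noiseless_activity):
        flights, stops = segment(noiseless_activity)
        bounds = pd.concat(
            [flights[["start_utc", "end_utc"]], stops[["start_utc", "end_utc"]]]
        ).sort_values("start_utc")
        assert (bounds["start_utc"].iloc[1:].to_numpy() == bounds["end_utc"].iloc[:-1].to_numpy()).all()
        t = noiseless_activity["timestamp_utc"]
        assert bounds["start_utc"].iloc[0] == t.iloc[0]
        assert bounds["end_utc"].iloc[-1] == t.iloc[-1] + pd.Timedelta(minutes=5)

    def test_duration_subadditive(self, itinerary):
        rec = simulate_activity(itinerary, GeneratorNoise(0.05, 0.02, 0.01))
        flights, _ = segment(rec)
        elapsed = (flights["end_utc"] - flights["start_utc"]) / pd.Timedelta(hours=1)
        assert (flights["duration_h"] <= elapsed + 1e-9).all()

    def test_long_57h_flight_recovered_exactly(self):
        # the longest observed autumn flight magnitude (~57 h), aligned to
        # the 5-minute recording grid so exact recovery is possible
        site1 = Site(56.2328, 16.4111, "2019-08-01", "2019-08-03 06:00")
        start = pd.Timestamp("2019-08-03 06:00")
        site2 = Site(14.7, -17.4, "2019-08-05 15:15", "2019-09-20")
        itin = ItinerarySpec((site1, site2), ((0, start, 57.25),), seed=0)
        rec = simulate_activity(itin, GeneratorNoise(), "2019-08-01", "2019-08-10")
        flights, _ = segment(rec)
        assert len(flights) == 1
        assert flights["duration_h"].iloc[0] == pytest.approx(57.25, abs=1e-9)


class TestSummaries:
    def test_single_flight_totals(self):
        flights = pd.DataFrame({"duration_h": [10.0]})
        stops = pd.DataFrame(columns=["duration_d", "role"])
        s = summarize_track(flights, stops)
        assert s["n_flights"] == 1 and s["total_flight_h"] == 10.0

    def test_median_flight_duration(self):
        flights = pd.DataFrame({"duration_h": [2.0, 4.0, 6.0]})
        stops = pd.DataFrame(columns=["duration_d", "role"])
        assert summarize_track(flights, stops)["median_flight_h"] == 4.0

    def test_no_flights_reported_missing(self):
        s = summarize_track(pd.DataFrame(columns=["duration_h"]),
                            pd.DataFrame(columns=["duration_d", "role"]))
        assert s["n_flights"] == 0 and np.isnan(s["median_flight_h"])

    def test_total_flight_time_increases_with_distance(self):
        # distance-proportional planted flights -> positive regression slope
        totals, dists = [], []
        for seed, n_stop in [(1, 1), (2, 2), (3, 3)]:
            itin = demo_itinerary(seed, n_stopovers=n_stop)
            rec = simulate_activity(itin, GeneratorNoise(0.05, 0.02, 0.01))
            flights, stops = segment(rec)
            totals.append(summarize_track(flights, stops)["total_flight_h"])
            dists.append(sum(d for _, _, d in itin.flights))
        cov = np.cov(dists, totals)[0, 1]
        assert cov > 0


def test_estimator_interface(noiseless_activity):
    seg = ActivitySegmenter(high_hour_threshold=30)
    assert seg.get_params()["high_hour_threshold"] == 30
    flights = seg.fit_transform(noiseless_activity)
    assert len(flights) == 4
    clone_params = seg.get_params()
    assert ActivitySegmenter(**clone_params).get_params() == clone_params
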