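import numpy as np
import pandas as pd
import pytest

from mdltrack import (
    BREEDING_SITE_LATLON,
    GeneratorNoise,
    ItinerarySpec,
    Site,
    make_itinerary,
    simulate_activity,
    simulate_light,
)

DEST_IBERIA = (36.8, -6.4)


def demo_itinerary(seed: int, n_stopovers: int = 3) -> ItinerarySpec:
    """Plover-like autumn itinerary: SE Sweden breeding site -> SW Iberia."""
    origin = Site(*BREEDING_SITE_LATLON, "2019-07-20", "2019-08-05 21:00")
    dest = Site(*DEST_IBERIA, "2019-08-20", "2020-02-20")
    return make_itinerary(origin, dest, n_stopovers=n_stopovers, season="autumn", seed=seed)


@pytest.fixture(scope="session")
def itinerary():
    return demo_itinerary(seed=1)


@pytest.fixture(scope="session")
def noiseless_activity(itinerary):
    return simulate_activity(itinerary, GeneratorNoise())


@pytest.fixture(scope="session")
def stationary_itinerary():
    """A bird sitting at 40N 5W across the autumn equinox."""
    site = Site(40.0, -5.0, "2019-08-15", "2019-11-15")
    return ItinerarySpec((site,), (), seed=0)


@pytest.fixture(scope="session")
def stationary_light(stationary_itinerary):
    return simulate_light(stationary_itinerary, sun_angle=-6.0, threshold=2.0,
                          sample_interval_min=5)


def make_records(hour0: str, scores) -> pd.DataFrame:
    """Activity records from a flat list of 5-min scores (None = missing)."""
    t0 = pd.Timestamp(hour0)
    rows = [
        {"timestamp_utc": t0 + i * pd.Timedelta(minutes=5), "score": s, "n_subsamples": 5}
        for i, s in enumerate(scores)
        if s is not None
    ]
    return pd.DataFrame(rows)
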