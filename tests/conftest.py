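import warnings

import numpy as np
import pandas as pd
import pytest

from mobifood.pipeline import PipelineConfig, run_all
from mobifood.synthetic_world import WorldConfig, make_world


@pytest.fixture(scope="session")
def world4():
    """Tiny 4-neighborhood world with well-separated FF propensities."""
    return make_world(WorldConfig(n_neighborhoods=4, n_poi_per_neighborhood=12, n_users=24, seed=7))


@pytest.fixture(scope="session")
def pipeline_artifacts(tmp_path_factory):
    """One modest full pipeline run shared across integration tests."""
    cfg = PipelineConfig(
        world=WorldConfig(n_neighborhoods=6, n_users=90, days=5, n_respondents=2000, seed=3),
        seed=3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_all(cfg, tmp_path_factory.mktemp("artifacts"))


def make_pings(user_id, times_min, lats, lons, day="2017-01-02"):
    """Ping frame from minutes-past-midnight plus coordinate arrays."""
    base = pd.Timestamp(day)
    return pd.DataFrame(
        {
            "user_id": user_id,
            "timestamp": [base + pd.Timedelta(minutes=float(m)) for m in times_min],
            "lat": np.asarray(lats, dtype=float),
            "lon": np.asarray(lons, dtype=float),
        }
    )


def random_ping_track(rng, n=50, lat0=34.0, lon0=-118.4):
    """Random dwell-and-jump track: cluster-scale moves with occasional jumps,
    built so cluster membership decisions are non-trivial at d_roam=50 m."""
    m_lat = 1.0 / 110_574.0  # deg per meter
    m_lon = 1.0 / (111_320.0 * np.cos(np.radians(lat0)))
    t, lat, lon = 0.0, lat0, lon0
    rows = []
    for _ in range(n):
        t += rng.uniform(1.0, 20.0)
        if rng.random() < 0.15:  # jump to a new dwell site
            lat += rng.normal(0, 400) * m_lat
            lon += rng.normal(0, 400) * m_lon
        else:  # roam near the current site at the decision-boundary scale
            lat += rng.normal(0, 25) * m_lat
            lon += rng.normal(0, 25) * m_lon
        rows.append((t, lat, lon))
    return rows
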