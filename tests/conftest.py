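import numpy as np
import pandas as pd
import pytest

from mesocam.synth import minshan_mini_config, simulate_survey


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mini_survey():
    """One deterministic minshan-mini survey shared across the session."""
    cfg = minshan_mini_config()
    photos, deployments, truth = simulate_survey(cfg)
    return cfg, photos, deployments, truth


def make_photos(rows):
    """Photo table from (station, species, timestamp[, n]) tuples."""
    recs = []
    for row in rows:
        st, sp, ts = row[:3]
        n = row[3] if len(row) > 3 else 1
        recs.append({"station_id": st, "species": sp,
                     "timestamp": pd.Timestamp(ts), "n_individuals": n})
    return pd.DataFrame(recs)


def make_deployments(rows):
    """Deployment table from (station, lat, lon, start, end[, speed]) tuples."""
    recs = []
    for row in rows:
        st, lat, lon, t0, t1 = row[:5]
        speed = row[5] if len(row) > 5 else "fast"
        recs.append({"station_id": st, "latitude": lat, "longitude": lon,
                     "elevation": None, "start": pd.Timestamp(t0),
                     "end": pd.Timestamp(t1), "camera_speed": speed,
                     "lure_dates": [pd.Timestamp(t0).normalize()]})
    return pd.DataFrame(recs)
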