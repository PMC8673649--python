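import numpy as np
import pandas as pd
import pytest

from whaletrack import geo, simulate


@pytest.fixture(scope="session")
def curve():
    return geo.TravelTimeCurve.isospeed()


@pytest.fixture(scope="session")
def network_4x4():
    return simulate.make_network(spacing_km=70.0, shape=(4, 4))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def noiseless_detections(stations: pd.DataFrame, curve, lon: float, lat: float,
                         origin: float = 1000.0, p: float = 0.99,
                         max_range: float = 150.0) -> pd.DataFrame:
    """Exact arrival times for a source at (lon, lat) on every in-range station."""
    rows = []
    for s in stations.itertuples():
        r = geo.great_circle_km(s.lon, s.lat, lon, lat)
        if r > max_range:
            continue
        rows.append({"station": s.id, "time": origin + curve.predict(r),
                     "rs": 6.5, "duration": 12.0, "p_true": p})
    return pd.DataFrame(rows).sort_values("time").reset_index(drop=True)
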