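import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from epeagree.types import ExposureUnit, PrecipSeries, Station, StationNetwork


def make_series(values, source_id="s", start="2011-01-01", qc=None):
    values = np.asarray(values, dtype=float)
    dates = pd.date_range(start, periods=len(values), freq="D")
    return PrecipSeries(source_id, dates, values, qc)


def make_network(specs, start="2011-01-01", n_days=None):
    """specs: list of (station_id, x, y, values) with equal-length values."""
    stations = []
    for sid, x, y, vals in specs:
        stations.append(Station(sid, x, y, make_series(vals, sid, start)))
    return StationNetwork(stations)


def square_unit(uid, x0, y0, side=1.0, **attrs):
    return ExposureUnit(uid, box(x0, y0, x0 + side, y0 + side), **attrs)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def demo_region():
    """Small but complete synthetic region shared by read-only tests."""
    from epeagree.synthetic import RegionConfig, generate_region

    cfg = RegionConfig(
        region_size_km=48.0,
        n_tracts_side=4,
        n_days=400,
        n_stations=12,
        seed=7,
    )
    return generate_region(cfg)
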