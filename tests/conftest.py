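import numpy as np
import pandas as pd
import pytest

from oxymetab.synthetic import (DepthSpec, DriverCoupling, LakeScenario,
                                simulate_lake)
from oxymetab.types import SensorSeries


def clean_scenario(days=14, depths=None, seed=0, **kw):
    """Noise- and tide-free scenario: estimator output should equal truth."""
    depths = depths or [
        DepthSpec(1.0, 120.0, -60.0, do_initial_um=200.0),
        DepthSpec(6.0, 80.0, -90.0, do_initial_um=150.0),
    ]
    start = pd.Timestamp("2016-03-01")
    defaults = dict(depths=depths, start=str(start),
                    end=str(start + pd.Timedelta(days=days)),
                    tidal_amplitude_um=0.0, noise_sd_um=0.0, seed=seed)
    defaults.update(kw)
    return LakeScenario(**defaults)


@pytest.fixture(scope="session")
def clean_bundle():
    """(scenario, series list, truth) for a two-week noiseless deployment."""
    sc = clean_scenario()
    series, truth = simulate_lake(sc)
    return sc, series, truth


@pytest.fixture(scope="session")
def coupled_scenario():
    """One year of drivers with wind -> response coupling at lag 1."""
    return LakeScenario(
        start="2016-01-01", end="2017-01-01",
        coupling=DriverCoupling("u10_ms", "response", lag_days=1,
                                coefficient=0.9, noise_sd=1.0),
        seed=11)


def make_series(index, do, temp=30.0, depth=1.0, cadence=10):
    """Small hand-built SensorSeries for unit tests."""
    frame = pd.DataFrame({"do_um": np.asarray(do, dtype=float),
                          "temp_c": np.broadcast_to(temp, len(index)).copy()},
                         index=pd.DatetimeIndex(index, name="timestamp"))
    return SensorSeries(depth_m=depth, data=frame, cadence_min=cadence)
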