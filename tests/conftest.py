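import numpy as np
import pandas as pd
import pytest

from firesmoke import SimScenario, run_pipeline, simulate_inputs


@pytest.fixture(scope="session")
def scenario():
    """Three-province, five-year scenario with the default calibration."""
    return SimScenario(n_provinces=3, seed=7)


@pytest.fixture(scope="session")
def bundle(scenario):
    return simulate_inputs(scenario)


@pytest.fixture(scope="session")
def result(bundle):
    """Default-config pipeline run on the synthetic bundle."""
    return run_pipeline(
        bundle.hourly, bundle.hotspots, bundle.population, bundle.visits
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def hourly_frame(station, province, date, values):
    """Build an hourly record frame for one station-day from a value list."""
    ts = pd.Timestamp(date) + pd.to_timedelta(range(len(values)), unit="h")
    return pd.DataFrame(
        {
            "station_id": station,
            "province": province,
            "timestamp": ts,
            "pm10": values,
        }
    )
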