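import numpy as np
import pandas as pd
import pytest

from passflow.config import PipelineConfig, SimConfig


@pytest.fixture
def pipe_config():
    return PipelineConfig()


@pytest.fixture
def sim_config():
    return SimConfig(rng_seed=42)


@pytest.fixture(scope="session")
def season():
    """One full synthetic campaign, shared read-only across tests."""
    from passflow import synthetic
    return synthetic.simulate_season(SimConfig(rng_seed=11))


@pytest.fixture
def small_weather():
    """Tiny weather table with hand-set covariates."""
    df = pd.DataFrame({
        "date": pd.date_range("2021-09-01", periods=6),
        "temp_c": [5.0, 10.0, 15.0, 8.0, 12.0, 20.0],
        "wind_heading_deg": [225.0, 45.0, 135.0, 225.0, 45.0, 315.0],
        "rain_mm": [0.0, 2.0, 0.0, 5.0, 0.0, 0.0],
        "windspeed_ms": [3.0, 1.0, 2.0, 6.0, 4.0, 2.0],
        "sunshine_min": [480.0, 0.0, 240.0, 120.0, 360.0, 480.0],
    })
    from passflow import weather as wm
    return wm.derive_covariates(df)
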