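from datetime import date

import pandas as pd
import pytest

from phenosync import synthetic


@pytest.fixture(scope="session")
def small_weather():
    """Two years of daily weather over 6 cells, deterministic."""
    cfg = synthetic.WeatherSimConfig(
        n_cells=6, date_start=date(2014, 1, 1), date_end=date(2015, 12, 31), seed=7
    )
    return synthetic.gen_weather(cfg, granularity="daily")


@pytest.fixture(scope="session")
def recovery_weather():
    """Weather in the regime where planted windows are recoverable."""
    cfg = synthetic.WeatherSimConfig(
        n_cells=40,
        date_start=date(2014, 1, 1),
        date_end=date(2015, 12, 31),
        noise_sd=6.0,
        seasonal_amplitude=4.0,
        seed=11,
    )
    return synthetic.gen_weather(cfg, granularity="daily")


@pytest.fixture(scope="session")
def hourly_weather():
    cfg = synthetic.WeatherSimConfig(
        n_cells=2, date_start=date(2015, 1, 1), date_end=date(2015, 3, 31), seed=3
    )
    return synthetic.gen_weather(cfg, granularity="hourly")


@pytest.fixture()
def constant_hourly():
    """Constant 5 degC, zero precipitation, hourly, one cell, 10 days."""
    stamps = pd.date_range("2015-03-01", "2015-03-10 23:00", freq="h")
    return pd.DataFrame(
        {"cell_id": "0_0", "timestamp": stamps, "temp_c": 5.0, "precip_mm": 0.0}
    )
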