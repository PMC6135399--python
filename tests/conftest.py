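import datetime as dt

import numpy as np
import pytest

from chiagrow import (
    ANTUMAPU,
    BIOMASS_COEFFICIENTS,
    DoubleLogisticCoefficients,
    WeatherDay,
    generate_weather,
)


@pytest.fixture
def sd1_biomass() -> DoubleLogisticCoefficients:
    """The SD1 biomass coefficient set used as a recovery truth."""
    return DoubleLogisticCoefficients.from_row(BIOMASS_COEFFICIENTS.loc["SD1"])


@pytest.fixture
def antumapu_weather() -> list[WeatherDay]:
    """A 121-day seeded summer weather series at the sowing-date site."""
    return generate_weather(ANTUMAPU, dt.date(2010, 12, 7), 121, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_day(date=dt.date(2011, 1, 1), tmin=10.0, tmax=24.0, **kw) -> WeatherDay:
    defaults = dict(u2=2.0, rn=15.0, g=0.0)
    defaults.update(kw)
    return WeatherDay(date=date, tmin=tmin, tmax=tmax, **defaults)
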