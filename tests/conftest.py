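import datetime as dt

import numpy as np
import pytest

from wheatdyn import datasets
from wheatdyn.phenothermal import WeatherSeries
from wheatdyn.synthetic_data import SyntheticConfig, make_experiment


@pytest.fixture(scope="session")
def coefficients():
    """Published logistic fit coefficients (16 treatment x variable rows)."""
    return datasets.fit_coefficients()


@pytest.fixture(scope="session")
def published_eigen():
    """Published fast-phase eigenvalue tables at printed precision."""
    return datasets.published_eigenvalues()


@pytest.fixture(scope="session")
def experiment():
    """Default synthetic experiment (two seasons, 5% noise, seed 42)."""
    return make_experiment(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def zero_noise_experiment():
    """Same experiment with all noise switched off (ground-truth closure)."""
    return make_experiment(SyntheticConfig(seed=42).zero_noise())


@pytest.fixture
def weather_from_means():
    """Factory: WeatherSeries with given daily mean temperatures."""

    def build(t_mean, start=dt.date(2020, 10, 1), season="test"):
        t_mean = np.asarray(t_mean, dtype=float)
        dates = [start + dt.timedelta(days=i) for i in range(t_mean.size)]
        return WeatherSeries.from_arrays(
            season=season,
            dates=dates,
            t_min=t_mean - 3.0,
            t_mean=t_mean,
            t_max=t_mean + 3.0,
        )

    return build
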