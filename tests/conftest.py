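import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import wheatideo as w
from wheatideo.experiments import site_sim_config

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def rr_params():
    return w.site_params("RR")


@pytest.fixture(scope="session")
def rr_weather(rr_params):
    """32 years of baseline Rothamsted-like weather (30 full seasons)."""
    return w.generate_series(rr_params, 32, seed=101)


@pytest.fixture(scope="session")
def rr_weather_2050(rr_params):
    params = w.apply_scenario(rr_params, w.scenario_2050("UK"))
    return w.generate_series(params, 32, seed=202)


@pytest.fixture(scope="session")
def rr_config():
    return site_sim_config("RR")


@pytest.fixture(scope="session")
def claire_ensemble(rr_weather, rr_config):
    return w.simulate_ensemble(w.CLAIRE, rr_weather, rr_config, n_seasons=10)


def constant_weather(n_years=2, tmin=12.0, tmax=22.0, rain=2.0, rad=12.0):
    """A flat synthetic series for deterministic single-season checks."""
    n = n_years * 365
    return w.WeatherSeries(
        year=np.repeat(np.arange(n_years), 365),
        doy=np.tile(np.arange(1, 366), n_years),
        tmin=np.full(n, float(tmin)), tmax=np.full(n, float(tmax)),
        rain=np.full(n, float(rain)), rad=np.full(n, float(rad)))


@pytest.fixture(scope="session")
def flat_weather():
    return constant_weather()
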