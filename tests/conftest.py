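import numpy as np
import pytest
from hypothesis import settings

import burnwindows as bw

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec():
    return bw.SyntheticClimateSpec(n_lat=4, n_lon=4, start="1981-01-01",
                                   end="1985-12-31", seed=42)


@pytest.fixture(scope="session")
def weather(small_spec):
    return bw.generate_weather_grid(small_spec)


@pytest.fixture(scope="session")
def fm_grid(weather):
    return bw.compute_fuel_moisture_grid(weather, spinup=90)


@pytest.fixture(scope="session")
def plans():
    return bw.generate_burn_plans(14, 8, seed=7)


@pytest.fixture(scope="session")
def envelopes(plans):
    return {
        "forest": bw.median_envelope(plans, bw.VEG_FOREST),
        "non-forest": bw.median_envelope(plans, bw.VEG_NONFOREST),
        "all": bw.median_envelope(plans, None),
    }


@pytest.fixture(scope="session")
def veg_mask(weather):
    return bw.generate_vegetation_mask(weather["lat"].values,
                                       weather["lon"].values, 0.5, seed=3)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
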