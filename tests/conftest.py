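import numpy as np
import pytest

from hygrotherm import PlumageOptics, allometry
from hygrotherm.scholander import ScholanderModel
from hygrotherm.synthetic import WeatherGenSpec, gen_weather, tree_swallow_models


@pytest.fixture(scope="session")
def morph():
    return allometry(18.9)


@pytest.fixture(scope="session")
def optics():
    return PlumageOptics(absorptance_dorsal=0.84, absorptance_ventral=0.80)


@pytest.fixture(scope="session")
def swallow_models():
    return tree_swallow_models()


@pytest.fixture(scope="session")
def humid_truth():
    """Generating model for humid-condition populations."""
    return ScholanderModel(lct=29.2, slope=-0.040, plateau=0.62,
                           sigma_below=0.057, sigma_above=0.057,
                           sigma_slope=0.008)


@pytest.fixture(scope="session")
def short_weather():
    """One synthetic breeding season of hourly weather."""
    return gen_weather(WeatherGenSpec(years=(2023,), seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
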