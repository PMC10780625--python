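import numpy as np
import pytest

from dendrostand.synthetic import ClimateScenario, generate_climate, generate_study


@pytest.fixture(scope="session")
def study():
    """The default synthetic study (seed 0), shared across tests."""
    return generate_study(0)


@pytest.fixture(scope="session")
def climate_1956_1997():
    return generate_climate(ClimateScenario(start_year=1956, end_year=1997, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
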