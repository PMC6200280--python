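import numpy as np
import pytest

from pd1tcr import RateParameters, builtin_scenario


@pytest.fixture(scope="session")
def default_params() -> RateParameters:
    return RateParameters()


@pytest.fixture(scope="session")
def fig3_scenario():
    return builtin_scenario("fig3_base")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20181024)
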