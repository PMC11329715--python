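import numpy as np
import pytest

from vipertherm import synthgen


@pytest.fixture(scope="session")
def default_roster():
    return synthgen.generate_roster(synthgen.default_population_configs(), seed=7)


@pytest.fixture(scope="session")
def default_trials(default_roster):
    return synthgen.generate_gradient_trials(default_roster, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
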