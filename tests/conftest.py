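import numpy as np
import pytest

from placentig.parameters import (
    HuvecParameters,
    ImmunizationParameters,
    table1_midpoint,
)
from placentig.transfer import simulate_transfer


@pytest.fixture(scope="session")
def midpoint_params():
    return table1_midpoint()


@pytest.fixture(scope="session")
def term_simulation(midpoint_params):
    """One full-gestation simulation at the optimized-range midpoints."""
    return simulate_transfer(midpoint_params)


@pytest.fixture(scope="session")
def huvec_params():
    return HuvecParameters()


@pytest.fixture(scope="session")
def imm_params():
    return ImmunizationParameters()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
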