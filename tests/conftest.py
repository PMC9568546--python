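import numpy as np
import pytest

from clonoscope import SimConfig, make_reference_fixtures, simulate


@pytest.fixture(scope="session")
def reference_fixtures():
    return make_reference_fixtures()


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort for round-trip and moment tests."""
    return simulate(SimConfig(seed=11, n_irradiated=4, n_control=2))


@pytest.fixture()
def rng():
    return np.random.default_rng(20221014)
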