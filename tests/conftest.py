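import numpy as np
import pytest

from spinrelax.synthetic import SyntheticSpec, generate_two_timescale_trajectory


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec()


@pytest.fixture(scope="session")
def default_trajectory(default_spec):
    return generate_two_timescale_trajectory(default_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
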