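import numpy as np
import pytest

from dmhs import scenarios
from dmhs.core import BoundarySpec, ParticleSystem, Phase


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_gas():
    system, topology, boundary = scenarios.fixture_generator(
        "random_gas", n=60, seed=7
    )
    return system, topology, boundary


@pytest.fixture
def open_box():
    return BoundarySpec((-100.0, -100.0), (100.0, 100.0), (False, False))
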