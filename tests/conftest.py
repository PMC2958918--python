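import numpy as np
import pytest

from mutrace.effects import resolve_model
from mutrace.population import InitialFitnessSpec, SubpopulationRateSet


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def baseline_model():
    """The study's baseline DFE: p_b = 3%, exp mean 0.01, gamma(0.6, 0.5)."""
    return resolve_model(0.03, 0.01, 0.6, 0.3)


@pytest.fixture
def ru1():
    return SubpopulationRateSet(
        rates=(0.0001, 0.0003, 0.001, 0.003, 0.01, 0.02, 0.03, 0.04, 0.06, 0.1)
    )


@pytest.fixture
def uniform_init():
    return InitialFitnessSpec()
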