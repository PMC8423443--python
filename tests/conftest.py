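import numpy as np
import pytest

from toxinwars import EcologicalParams, constitutive, nutrient_sensing, \
    quorum_sensing, toxin_sensing


@pytest.fixture(scope="session")
def params():
    """Standard parameter set."""
    return EcologicalParams()


@pytest.fixture(scope="session")
def fast_params():
    """Short, coarse competitions for property tests."""
    return EcologicalParams(t_end=6.0, dt=0.02)


@pytest.fixture(scope="session")
def strategy_pool():
    """A small mixed pool of valid strategies covering all modes."""
    return [
        constitutive(0.0), constitutive(0.1), constitutive(0.31),
        constitutive(0.5), constitutive(1.0),
        nutrient_sensing(0.0, 0.5, 0.3), nutrient_sensing(0.6, 0.1, 0.5),
        toxin_sensing(0.02, 0.7, 0.01), toxin_sensing(0.3, 0.9, 1.0),
        quorum_sensing(0.0, 0.6, 0.3), quorum_sensing(0.6, 0.0, 0.2),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
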