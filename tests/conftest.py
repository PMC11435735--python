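import numpy as np
import pytest

from mibci.preprocess import bandpass, segment
from mibci.synthdata import SimulationConfig, generate_session


@pytest.fixture(scope="session")
def default_session():
    """One default mi-vs-rest session (erd 0.5, snr 5 dB, seed 0)."""
    return generate_session(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def default_epochs(default_session):
    """Band-passed, segmented epochs of the default session."""
    return segment(bandpass(default_session))


@pytest.fixture(scope="session")
def lr_session():
    """A left-vs-right session for two-hand decoding tests."""
    return generate_session(
        SimulationConfig(task_mode="left_vs_right", seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
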