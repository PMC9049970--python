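import numpy as np
import pytest

from trrkit import synthdata as sd


@pytest.fixture(scope="session")
def protocol():
    return sd.ProtocolParams()


@pytest.fixture(scope="session")
def observer():
    return sd.ObserverModel()


@pytest.fixture(scope="session")
def staircase():
    return sd.StaircaseSpec()


@pytest.fixture(scope="session")
def behavior_and_truth(protocol, observer, staircase):
    """One deterministic two-run session (easy + hard)."""
    return sd.simulate_behavior(protocol, observer, staircase, seed=42)


@pytest.fixture(scope="session")
def clean_session(protocol):
    """Session with no lapses and moderate noise, for pipeline tests."""
    obs = sd.ObserverModel(lapse_prob_easy=0.0, lapse_prob_hard=0.0)
    return sd.simulate_session(
        seed=7, protocol=protocol, observer=obs, n_voxels=6, n_background=12
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
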