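import numpy as np
import pytest

from neurocue import synth, task


@pytest.fixture(scope="session")
def default_observer():
    return task.ObserverParams()


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-profile contact dataset shared by clustering/stats tests."""
    return synth.generate_contacts(
        n_per_cluster={"visual": 12, "sustained": 12, "late_accumulation": 12,
                       "reorienting": 12, "conscious_report": 12, "null": 12},
        n_trials=80, noise_sd=1.0, seed=7)


@pytest.fixture(scope="session")
def session_trials():
    return task.generate_session(task.SessionConfig(blocks=1), seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
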