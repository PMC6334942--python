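import numpy as np
import pytest

from saccadapt import build_protocol
from saccadapt.synthetic_data import simulate_cohort, simulate_session


@pytest.fixture(scope="session")
def reactive_protocol():
    return build_protocol("reactive", "down-up")


@pytest.fixture(scope="session")
def session_trials(reactive_protocol):
    """One simulated reactive down-up session with default noise."""
    return simulate_session(reactive_protocol, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """Six-participant cohort across all four conditions (shared, read-only)."""
    return simulate_cohort(6, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
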