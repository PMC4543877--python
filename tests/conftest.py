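"""Shared fixtures: expensive simulations are session-scoped so the suite
runs a handful of long trials once and analyzes them from many tests."""

import numpy as np
import pytest

from antcpg import default_network, simulate_trial
from antcpg.experiments import ExperimentConfig, resolve_patterns, run_condition


@pytest.fixture(scope="session")
def mc_patterns():
    return resolve_patterns("Mc")


@pytest.fixture(scope="session")
def mc_trial(mc_patterns):
    """Standard intact Mc run: 60 s after a 5 s transient, seed 3."""
    spec = default_network("intact")
    return simulate_trial(spec, mc_patterns, duration=60.0, seed=3, transient=5.0)


@pytest.fixture(scope="session")
def intact_summary():
    return run_condition(ExperimentConfig(condition="intact", variant="Mc", seed=5))


@pytest.fixture(scope="session")
def ablated_summary():
    return run_condition(ExperimentConfig(condition="ablated", variant="Mc", seed=5))


@pytest.fixture(scope="session")
def mmsd_summary():
    return run_condition(ExperimentConfig(condition="intact", variant="Mmsd", seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
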