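"""Shared fixtures: default model inputs and the expensive simulations.

Session-scoped fixtures hold the runs reused across files: the default
single-cell episode (deterministic), a 2 h / 10,000-cell population run
and a scaled-down 24 h / 1,000-cell run for the slow protein dynamics.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from strpfr import (
    ReactorConfig,
    SimulationParameters,
    default_trp_operon,
    population_trajectory,
    run_population,
    simulate_episode,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> SimulationParameters:
    return SimulationParameters()

@pytest.fixture(scope="session")
def reactor() -> ReactorConfig:
    return ReactorConfig()


@pytest.fixture(scope="session")
def operon():
    return default_trp_operon()


@pytest.fixture(scope="session")
def episode(params, operon):
    """The default induction episode (the shared look-up table)."""
    return simulate_episode(params, operon)


@pytest.fixture(scope="session")
def pop2h(reactor):
    """2 h of the full 10,000-cell distribution model, seed 1."""
    return run_population(reactor, duration=2 * 3600.0, seed=1)


@pytest.fixture(scope="session")
def smallpop(episode):
    """A 40-cell run small enough for brute-force cross-checks."""
    reactor = ReactorConfig(n0=40)
    return run_population(reactor, duration=1800.0, seed=3)


@pytest.fixture(scope="session")
def longrun(episode):
    """Scaled-down long run (1,000 cells, 24 h) with its trajectories.

    Per-capita levels are independent of the cell count, so the slow
    protein equilibration is resolved at a tenth of the census.
    """
    reactor = ReactorConfig(n0=1000)
    pop = run_population(reactor, duration=24 * 3600.0, seed=7, sample_dt=60.0)
    grid = np.arange(0.0, 24 * 3600.0 + 1, 300.0)
    expr = population_trajectory(pop, episode, grid)
    return pop, expr
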