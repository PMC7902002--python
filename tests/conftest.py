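"""Shared fixtures for the icbreed test suite.

Expensive session-scoped fixtures (founder simulations and the replicated
desk-scale comparison run used by the acceptance tests) live here so they
are built once per session.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from icbreed.designs import desk_designs, medium_designs
from icbreed.experiment import RunConfig, run_experiment
from icbreed.genome import desk_genome_params, simulate_founders
from icbreed.traits import sample_architecture

# Deterministic hypothesis runs: no example database, no timing flakiness.
settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def desk_params():
    return desk_genome_params()


@pytest.fixture(scope="session")
def founders_A(desk_params):
    return simulate_founders(desk_params, 40, seed=1234, crop_id="A")


@pytest.fixture(scope="session")
def founders_B(desk_params):
    return simulate_founders(desk_params, 40, seed=5678, crop_id="B")


@pytest.fixture(scope="session")
def arch_A(founders_A):
    rng = np.random.default_rng(7)
    return sample_architecture(founders_A, 0.9, rng)


@pytest.fixture(scope="session")
def full_designs():
    return medium_designs()


@pytest.fixture(scope="session")
def desk_design_set():
    return desk_designs()


@pytest.fixture(scope="session")
def desk_metrics():
    """Replicated desk-scale comparison of all five arms at both correlations.

    This is the acceptance-criterion workload: 10 seed-paired replicates,
    20-year burn-in, 20-year future, genetic correlations 0.9 and 0.4.
    It takes a few minutes and is shared by every test that needs it.
    """
    cfg = RunConfig(
        base_seed=1, preset="desk", corrs=(0.9, 0.4), n_reps=10,
        burnin_years=20, future_years=20,
    )
    return run_experiment(cfg)
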