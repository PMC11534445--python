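"""Shared fixtures: default parameters, solver settings, and cached runs."""

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

import scavsim as sv

hyp_settings.register_profile("suite", derandomize=True, max_examples=100)
hyp_settings.load_profile("suite")


@pytest.fixture(scope="session")
def params() -> sv.ParameterSet:
    return sv.ParameterSet()


@pytest.fixture(scope="session")
def run_settings() -> sv.RunSettings:
    return sv.RunSettings()


@pytest.fixture(scope="session")
def short_settings() -> sv.RunSettings:
    """Shorter horizon for cross-check tests that only need dynamics, not equilibria."""
    return sv.RunSettings(t_end=60.0)


@pytest.fixture(scope="session")
def veg_only_trajectory(params, run_settings) -> sv.Trajectory:
    """Vegetation-only 250-yr run from V0 = 1 (logistic limit)."""
    return sv.solve(sv.StateVector(V=1.0), params, run_settings, "veg-only")


@pytest.fixture(scope="session")
def full_trajectory(params, run_settings) -> sv.Trajectory:
    """Default full-web scenario (boar and wolf present, medium hunting)."""
    config = sv.ScenarioConfig()
    return sv.run_scenarios([config], params, run_settings)[0]


@pytest.fixture(scope="session")
def random_states() -> list[sv.StateVector]:
    """Deterministic sweep of strictly positive states for oracle comparisons."""
    rng = np.random.default_rng(20240831)
    return [
        sv.StateVector.from_array(rng.uniform(1e-3, 8.0, size=5)) for _ in range(1000)
    ]
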