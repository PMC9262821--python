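"""Shared fixtures: expensive steady states are computed once per session."""

import numpy as np
import pytest
from hypothesis import settings

from saliduct import (SimulationConfig, build_geometry, build_simplified,
                      make_fixture, run_to_steady_state)

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_config():
    """Reference configuration: 4 acini, calibrated parameters."""
    fx = make_fixture("paper-default", seed=0)
    return SimulationConfig(geometry=fx.geometry, params=fx.params,
                            boundary=fx.boundary)


@pytest.fixture(scope="session")
def full_steady(paper_config):
    """Unstimulated steady state of the full duct model."""
    return run_to_steady_state(paper_config)


@pytest.fixture(scope="session")
def simplified_steady(paper_config):
    """Steady state of the two-compartment simplification."""
    return run_to_steady_state(build_simplified(paper_config))


@pytest.fixture(scope="session")
def mini_config():
    """Small 4-cell duct (2 ID + 2 SD) for fast transient tests."""
    fx = make_fixture("mini-duct", seed=0)
    return SimulationConfig(geometry=fx.geometry, params=fx.params,
                            boundary=fx.boundary)


@pytest.fixture(scope="session")
def mini_steady(mini_config):
    return run_to_steady_state(mini_config)
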