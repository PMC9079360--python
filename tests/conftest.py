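import dataclasses

import pytest
from hypothesis import HealthCheck, settings

from nfdetox.membrane import canonical_membrane
from nfdetox.optimize import OptimizationConfig, grid_scan
from nfdetox.properties import ChannelGeometry, SolutionConditions
from nfdetox.synthdata import calibrate_fixture, feed_from_spec, model_solution_fixture

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def membrane():
    return canonical_membrane()


@pytest.fixture(scope="session")
def no_de_membrane(membrane):
    """Membrane with the dielectric-exclusion term switched off (eps* = eps_b)."""
    return dataclasses.replace(membrane, oriented_layer_dielectric=80.0)


@pytest.fixture(scope="session")
def conditions():
    return SolutionConditions()


@pytest.fixture(scope="session")
def geometry():
    return ChannelGeometry()


@pytest.fixture(scope="session")
def model_feed():
    return model_solution_fixture()


@pytest.fixture(scope="session")
def calibration():
    """The P1-anchored fixture calibration (shared across tests: ~2 s)."""
    return calibrate_fixture()


@pytest.fixture(scope="session")
def calibrated_feed(calibration):
    return feed_from_spec(calibration.spec)


@pytest.fixture(scope="session")
def grid_result(calibrated_feed, membrane):
    """The full 100x100 operating-point scan (shared: the expensive step)."""
    return grid_scan(calibrated_feed, OptimizationConfig(), membrane)
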