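import numpy as np
import pytest

from beesearch import SimulatorConfig, make_fixture
from beesearch.preprocess import Trajectory


@pytest.fixture(scope="session")
def test_area():
    return make_fixture("test-area")


@pytest.fixture(scope="session")
def toy_area():
    return make_fixture("two-edge-toy")


@pytest.fixture(scope="session")
def edgeless():
    return make_fixture("edgeless")


@pytest.fixture(scope="session")
def short_config():
    """A fast simulator configuration for tests that only need path shape,
    not the full-length study conditions."""
    return SimulatorConfig(n_steps=2000)


def random_walk_trajectory(rng, n=200, step_sd=30.0, bee_id="b", group="g") -> Trajectory:
    """A generic random-walk trajectory (not the search-flight model) for
    mass-conservation / consistency checks."""
    steps = rng.normal(0.0, step_sd, size=(n - 1, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    t = np.arange(n) * 3.0
    return Trajectory(bee_id, group, t, xy[:, 0], xy[:, 1])
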