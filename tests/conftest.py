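import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import brainsongs as bs

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def dmf_params():
    return bs.DmfParameters()


@pytest.fixture(scope="session")
def two_node_zero():
    """Two uncoupled regions: the isolated-node configuration."""
    return bs.StructuralConnectome(np.zeros((2, 2)))


@pytest.fixture(scope="session")
def toy_connectome():
    return bs.make_connectome(5, family="community", seed=3)


@pytest.fixture(scope="session")
def tuned_isolated(two_node_zero, dmf_params):
    """FIC weights for the uncoupled pair, shared across tests."""
    return bs.fic_tune(two_node_zero, dmf_params, G=0.0, seed=1)


@pytest.fixture(scope="session")
def isolated_trajectory(two_node_zero, dmf_params, tuned_isolated):
    """A 30 s isolated-node simulation reused by several tests."""
    traj = bs.simulate_dmf(two_node_zero, dmf_params, tuned_isolated,
                           32_000.0, dt=0.1, seed=7)
    return traj.discard(2_000.0)
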