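import numpy as np
import pytest

from ringrecal.network_core import (
    converge_bump,
    default_network,
    rotation_ring_rates,
)


@pytest.fixture(scope="session")
def full_net():
    """Default calibrated full network (n=256) with its converged bump template."""
    params = default_network(n=256)
    template = converge_bump(params, duration=2.0)
    r_cw, r_ccw = rotation_ring_rates(template, 0.0, params)
    return params, template, (r_cw, r_ccw)


@pytest.fixture(scope="session")
def trained_plastic_net():
    """Association-trained plastic network (n=128), shared across tests.

    Tests must not mutate it directly; use ``net.snapshot()``.
    """
    from ringrecal.angles import TWO_PI
    from ringrecal.plastic_network import build_plastic_network, train_association

    lap = TWO_PI / 0.5
    net = build_plastic_network(n=128, seed=0)
    return train_association(net, duration=4 * lap, v=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
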