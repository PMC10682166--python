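import numpy as np
import pytest

import savanna_patterns as sp


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def grid64():
    return sp.SpatialGrid(n=64)


@pytest.fixture(scope="session")
def grid256():
    return sp.SpatialGrid(n=256)


@pytest.fixture(scope="session")
def gf_params():
    """Resource-limited grass-forest model at the standard bifurcation slice."""
    return sp.default_params("RL-GF", alpha=4.5, r=0.84)


@pytest.fixture(scope="session")
def top_row_kernels():
    """Fire narrower than seed dispersal, resource competition widest."""
    return sp.gaussian_kernels(sigma_w=0.025, sigma_f=0.1, sigma_r=0.15)


@pytest.fixture(scope="session")
def simulation_preset():
    return sp.load_preset("fig4")


def random_simplex_states(rng, n):
    """Uniform random points on the 4-simplex."""
    x = rng.dirichlet(np.ones(4), size=n)
    return x
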