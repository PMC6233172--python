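import numpy as np
import pytest

from coexsim.calibration import default_pools
from coexsim.dynamics import SimulationConfig, prepare_world
from coexsim.species import build_trait_adjacency, generate_species_pool


@pytest.fixture(scope="session")
def pools():
    return default_pools(seed=0)


@pytest.fixture(scope="session")
def adj():
    # smaller calibration sample than the production default; same estimator
    return build_trait_adjacency(seed=1, n_calibration_pairs=50_000)


@pytest.fixture(scope="session")
def small_pool(pools):
    return generate_species_pool(pools, n_total=800, tardigrade_count=4,
                                 trajectory="heating", seed=2)


@pytest.fixture(scope="session")
def desk_world(adj):
    """One populated desk-scale world shared by read-only tests."""
    cfg = SimulationConfig.desk_scale(seed=5, n_localities=(12, 12))
    world, _ = prepare_world(cfg)
    return world


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
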