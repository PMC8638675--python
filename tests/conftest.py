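import numpy as np
import pytest

from vaxsae.car import AdjacencyGraph
from vaxsae.mcmc import MCMCConfig
from vaxsae.synthetic import CountryConfig, generate_country

# 3-district path graph shared by the oracle-equivalence tests
W_PATH3 = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)


@pytest.fixture(scope="session")
def path3_graph():
    return AdjacencyGraph(W_PATH3)


@pytest.fixture(scope="session")
def small_country():
    """A 6-district, 60-cluster country reused across module tests."""
    cfg = CountryConfig(
        n_districts=6, extent_km=(150.0, 150.0), n_clusters_total=60, seed=3
    )
    return generate_country(cfg)


@pytest.fixture(scope="session")
def quick_mcmc():
    """Short sampler settings for structural (non-oracle) tests."""
    return MCMCConfig(n_chains=2, n_warmup=300, n_keep=300)
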