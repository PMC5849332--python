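import numpy as np
import pytest

from ndanet.atlas import CoexpressionNetwork
from ndanet.synthdata import SimScenario, make_fixture, simulate_atlas, simulate_catalog


@pytest.fixture(scope="session")
def chain_bundle():
    """Engineered grouping fixture: chain {A,B,C}, anti-pair D/E, isolated F, far pair G/H."""
    return make_fixture("grouping_chain", seed=0)


@pytest.fixture(scope="session")
def chain_network(chain_bundle):
    _, _, atlas, _, _ = chain_bundle
    return CoexpressionNetwork(atlas)


@pytest.fixture(scope="session")
def null_small():
    """200 regions x 50 samples, no planted structure."""
    sc = SimScenario(n_regions=200, n_samples=50, seed=5)
    rng = sc.rng()
    catalog = simulate_catalog(sc, rng)
    atlas, truth = simulate_atlas(sc, catalog, rng)
    return sc, catalog, atlas, truth


@pytest.fixture(scope="session")
def null_small_network(null_small):
    _, _, atlas, _ = null_small
    return CoexpressionNetwork(atlas)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
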