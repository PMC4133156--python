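import numpy as np
import pytest

from scboolnet import (
    LearningConfig,
    binarize,
    gen_cells,
    learn_all,
    make_ground_truth,
    normalize_ct,
)
from scboolnet.io import load_seed_network


@pytest.fixture(scope="session")
def seed_network():
    return load_seed_network()


@pytest.fixture(scope="session")
def small8():
    return make_ground_truth("small8")


@pytest.fixture(scope="session")
def small8_cells(small8):
    """Expression + latent binary matrices at the standard study conditions
    (96 cells, 5% bit-flip noise), fixed generation seed."""
    em, latent = gen_cells(small8, seed=1)
    return em, latent


@pytest.fixture(scope="session")
def small8_binary(small8_cells):
    em, _ = small8_cells
    return binarize(normalize_ct(em))


@pytest.fixture(scope="session")
def small8_learned(small8, small8_binary):
    cfg = LearningConfig(theta=0.85, refinement_pool=tuple(small8.network.gene_ids))
    return learn_all(small8.network, small8_binary, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_signed_digraph(rng, n_nodes=8, n_edges=16):
    """Random signed digraph helper shared by oracle-equivalence tests."""
    from scboolnet.network import Node, SignedNetwork

    genes = [f"g{i}" for i in range(n_nodes)]
    edges = {}
    n_edges = min(n_edges, n_nodes * n_nodes)
    while len(edges) < n_edges:
        a = genes[int(rng.integers(n_nodes))]
        b = genes[int(rng.integers(n_nodes))]
        edges[(a, b)] = int(rng.choice([-1, 1]))
    return SignedNetwork([Node(g) for g in genes], edges)
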