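import numpy as np
import pytest

from mvgat.multiview_graph import EdgeSet, MultiViewNetwork
from mvgat.synthetic_data import fixture_toy_network


@pytest.fixture(scope="session")
def toy_network():
    return fixture_toy_network()


def random_edge_set(rng: np.random.Generator, n_nodes: int, p: float = 0.35) -> EdgeSet:
    iu, ju = np.triu_indices(n_nodes, k=1)
    keep = rng.random(iu.size) < p
    return EdgeSet.from_pairs(zip(iu[keep], ju[keep]), n_nodes)


def random_network(rng: np.random.Generator, n_nodes: int = 10, n_views: int = 2,
                   n_feat: int = 5, n_classes: int = 2) -> MultiViewNetwork:
    views = [random_edge_set(rng, n_nodes) for _ in range(n_views)]
    return MultiViewNetwork(
        node_ids=[f"n{i}" for i in range(n_nodes)],
        features=rng.normal(size=(n_nodes, n_feat)),
        labels=rng.integers(0, n_classes, n_nodes).astype(np.intp),
        views=views,
        train_mask=np.ones(n_nodes, dtype=bool),
    )
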