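import numpy as np
import pytest

from ppialign.model import ElementalSimilarity, Network


def net(edges, name="net", extra=()):
    """Shorthand: build a Network from label pairs."""
    return Network.from_edges(name, edges, extra_nodes=extra)


@pytest.fixture
def triangle():
    return net([("a", "b"), ("b", "c"), ("a", "c")], "tri")


@pytest.fixture
def path3():
    return net([("a", "b"), ("b", "c")], "path")


@pytest.fixture
def edge2():
    return net([("u", "v")], "edge")


def random_net(rng, n, p=0.4, name="rand"):
    """Random ER network; guarantees at least one edge."""
    labels = [f"n{i}" for i in range(n)]
    while True:
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(len(iu)) < p
        edges = [(labels[i], labels[j]) for i, j in zip(iu[mask], ju[mask])]
        if edges:
            return net(edges, name, extra=labels)


def random_H(rng, nA, nB):
    H = rng.random((nA, nB))
    H[H < 0.2] = 0.0
    if not (H > 0).any():
        H[0, 0] = 1.0
    return ElementalSimilarity(H)
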