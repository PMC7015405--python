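import numpy as np
import pytest

from netdist import Graph


@pytest.fixture
def k3() -> Graph:
    """Complete graph on 3 vertices."""
    return Graph.from_edges(3, [(0, 1), (1, 2), (0, 2)])


@pytest.fixture
def p3() -> Graph:
    """Path 0-1-2."""
    return Graph.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def star5() -> Graph:
    """Star on 5 vertices with center 0."""
    return Graph.from_edges(5, [(0, i) for i in range(1, 5)])


def random_graph(rng: np.random.Generator, n: int, p: float) -> Graph:
    """Erdős–Rényi draw for property tests (independent of netdist.ensembles)."""
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < p
    return Graph.from_edges(n, zip(iu[mask].tolist(), ju[mask].tolist()))


def random_connected_graph(rng: np.random.Generator, n: int, p: float) -> Graph:
    """Random spanning tree plus ER edges: connected by construction."""
    edges = set()
    order = rng.permutation(n)
    for i in range(1, n):
        j = order[int(rng.integers(i))]
        u, v = int(order[i]), int(j)
        edges.add((min(u, v), max(u, v)))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < p
    edges.update(zip(iu[mask].tolist(), ju[mask].tolist()))
    return Graph.from_edges(n, edges)
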