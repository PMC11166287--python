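import itertools

import numpy as np
import pytest

from grnbool.netcore import DirectedNetwork


def net_from_edges(n, edges, **kw):
    adj = np.zeros((n, n), dtype=np.int8)
    for r, t in edges:
        adj[r, t] = 1
    return DirectedNetwork(adj, **kw)


def code_to_adjacency(code: int) -> np.ndarray:
    """3-node adjacency from the 6-bit tricode over nodes (v, u, w) = (0, 1, 2)."""
    adj = np.zeros((3, 3), dtype=np.int8)
    bits = [(0, 1), (1, 0), (0, 2), (2, 0), (1, 2), (2, 1)]
    for k, (a, b) in enumerate(bits):
        if (code >> k) & 1:
            adj[a, b] = 1
    return adj


def canonical_form(adj: np.ndarray) -> tuple:
    """Lexicographically minimal relabelling of a 3-node digraph."""
    best = None
    for perm in itertools.permutations(range(3)):
        p = list(perm)
        relab = adj[np.ix_(p, p)]
        key = tuple(relab.flatten().tolist())
        if best is None or key < best:
            best = key
    return best


def vertex_orbits(adj: np.ndarray) -> int:
    """Number of vertex orbits under the automorphism group of a 3-node digraph."""
    autos = [
        perm
        for perm in itertools.permutations(range(3))
        if np.array_equal(adj[np.ix_(list(perm), list(perm))], adj)
    ]
    parent = list(range(3))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for perm in autos:
        for v in range(3):
            a, b = find(v), find(perm[v])
            if a != b:
                parent[a] = b
    return len({find(v) for v in range(3)})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
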