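"""Directed influence-graph data model and triadic-census machinery.

A candidate gene regulatory network is a directed graph over ``n`` genes,
stored as a dense boolean adjacency matrix: entry ``(r, t) == 1`` means gene
``r`` regulates gene ``t`` (rows are regulators, columns are targets).
Self-loops are forbidden and every gene is allowed at most ``max_regulators``
incoming edges.

The module also computes the topological feature vector used as an
optimisation prior — edge density, capped in/out-degree histograms and the
census of connected three-node subgraphs (triads) — together with an
incremental O(Delta) census update applied after single-edge mutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TRIAD_LABELS",
    "CONNECTED_TRIAD_MASK",
    "DEFAULT_MAX_REGULATORS",
    "DirectedNetwork",
    "TriadCensus",
    "TopologyFeatures",
    "tricode",
    "map_tricode_to_type",
    "count_triads",
    "count_local_triads",
    "apply_edge_mutation",
    "compute_topology_features",
]

DEFAULT_MAX_REGULATORS = 10
DEGREE_CAP = 10  # degree histograms use bins 0..10, larger degrees fold into 10

#: Canonical MAN ordering of the 16 triad isomorphism classes.  The label is
#: "<mutual><asymmetric><null>" edge counts plus a qualifier (Cycle,
#: Transitive, Up, Down) where the digit string is ambiguous.
TRIAD_LABELS = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)

#: Triad types counted by the connected-triple traversal (003, 012 and 102
#: have fewer than two undirected links and can never arise there).
CONNECTED_TRIAD_MASK = np.array(
    [label not in ("003", "012", "102") for label in TRIAD_LABELS], dtype=bool
)

# 64-entry lookup from the 6-bit edge code of an ordered node triple (v,u,w)
# to its triad class.  Bit weights follow
#   code = E(v,u) + 2 E(u,v) + 4 E(v,w) + 8 E(w,v) + 16 E(u,w) + 32 E(w,u)
# The table is the standard one from the sociometric literature; it is
# re-derived by brute-force isomorphism classification in the test suite.
_TRICODE_TO_TYPE = np.array(
    [x - 1 for x in (
        1, 2, 2, 3, 2, 4, 6, 8, 2, 6, 5, 7, 3, 8, 7, 11,
        2, 6, 4, 8, 5, 9, 9, 13, 6, 10, 9, 14, 7, 14, 12, 15,
        2, 5, 6, 7, 6, 9, 10, 14, 4, 9, 9, 12, 8, 13, 14, 15,
        3, 7, 8, 11, 7, 12, 14, 15, 8, 14, 13, 15, 11, 15, 15, 16,
    )],
    dtype=np.int64,
)


class InvalidTripleError(ValueError):
    """Raised when a triad query names duplicate node indices."""


@dataclass
class DirectedNetwork:
    """Boolean adjacency structure of a candidate influence graph.

    Parameters
    ----------
    adjacency
        ``n x n`` 0/1 integer matrix; ``adjacency[r, t] == 1`` means gene
        ``r`` regulates gene ``t``.  The diagonal must be zero.
    gene_names
        Ordered, unique identifiers aligned with the matrix axes.  Defaults
        to ``G1..Gn``.
    max_regulators
        Hard cap on the in-degree (column sums) of every gene.
    """

    adjacency: np.ndarray
    gene_names: list[str] | None = None
    max_regulators: int = DEFAULT_MAX_REGULATORS

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        self.adjacency = adj.astype(np.int8)
        if np.any(np.diag(self.adjacency)):
            raise ValueError("self-loops are not allowed in candidate networks")
        n = self.adjacency.shape[0]
        if self.gene_names is None:
            self.gene_names = [f"G{i + 1}" for i in range(n)]
        if len(self.gene_names) != n:
            raise ValueError("gene_names length must match adjacency size")
        if len(set(self.gene_names)) != n:
            raise ValueError("gene_names must be unique")
        indeg = self.adjacency.sum(axis=0)
        if indeg.max(initial=0) > self.max_regulators:
            raise ValueError(
                f"in-degree cap {self.max_regulators} violated "
                f"(max observed {int(indeg.max())})"
            )

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    def density(self) -> float:
        """Edge probability over all ordered pairs (denominator n^2)."""
        return self.n_edges / self.n**2

    def in_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def out_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def undirected(self) -> np.ndarray:
        """Symmetrised 0/1 adjacency of the underlying undirected graph."""
        a = self.adjacency
        return (a | a.T).astype(np.int8)

    def copy(self) -> "DirectedNetwork":
        return DirectedNetwork(
            self.adjacency.copy(), list(self.gene_names), self.max_regulators
        )

    def edges(self) -> list[tuple[int, int]]:
        rows, cols = np.nonzero(self.adjacency)
        return list(zip(rows.tolist(), cols.tolist()))


@dataclass
class TriadCensus:
    """Counts of the 16 triad classes plus per-pair contribution table.

    ``counts[k]`` is the number of connected node triples classified as
    ``TRIAD_LABELS[k]``; disconnected classes (003/012/102) stay zero under
    the connected-triple traversal.  ``pair_count[v, u, k]`` records how many
    counted triads of type ``k`` were credited to the ordered pair ``(v, u)``;
    each counted triad credits its three unordered node pairs exactly once, so
    the tensor sums to three times the census.
    """

    counts: np.ndarray
    pair_count: np.ndarray = field(repr=False)

    def copy(self) -> "TriadCensus":
        return TriadCensus(self.counts.copy(), self.pair_count.copy())


@dataclass
class TopologyFeatures:
    """Density, capped degree histograms and the normalised triad census."""

    density: float
    in_hist: np.ndarray
    out_hist: np.ndarray
    census_norm: np.ndarray

    def as_vector(self) -> np.ndarray:
        return np.concatenate(
            [[self.density], self.in_hist, self.out_hist, self.census_norm]
        )


def tricode(net: DirectedNetwork, v: int, u: int, w: int) -> int:
    """6-bit edge code of the ordered triple (v, u, w).

    code = E(v,u) + 2 E(u,v) + 4 E(v,w) + 8 E(w,v) + 16 E(u,w) + 32 E(w,u)
    """
    if len({v, u, w}) != 3:
        raise InvalidTripleError(f"triple ({v}, {u}, {w}) has duplicate nodes")
    a = net.adjacency
    return int(
        a[v, u]
        + 2 * a[u, v]
        + 4 * a[v, w]
        + 8 * a[w, v]
        + 16 * a[u, w]
        + 32 * a[w, u]
    )


def map_tricode_to_type(code: int) -> str:
    """Triad label for a 6-bit edge code."""
    if not 0 <= code <= 63:
        raise ValueError("tricode must be in 0..63")
    return TRIAD_LABELS[_TRICODE_TO_TYPE[code]]


def _neighbor_sets(und: np.ndarray) -> list[set[int]]:
    return [set(np.nonzero(row)[0].tolist()) for row in und]


def count_triads(net: DirectedNetwork) -> TriadCensus:
    """Census of connected triads plus the per-pair contribution table.

    Traverses every connected triple of the undirected projection exactly
    once (subquadratic in sparse graphs: O(Delta * |E|)) and classifies it
    with the tricode lookup.  Triples whose projection is disconnected are
    never visited, so the 003/012/102 slots stay zero.
    """
    n = net.n
    counts = np.zeros(16, dtype=np.int64)
    pair_count = np.zeros((n, n, 16), dtype=np.int64)
    a = net.adjacency
    und = net.undirected()
    nbrs = _neighbor_sets(und)
    for v in range(n):
        nv = nbrs[v]
        for u in nv:
            if u <= v:
                continue
            s = nv | nbrs[u]
            for w in s:
                if not (u < w or (v < w and w not in nv)):
                    continue
                code = (
                    a[v, u]
                    + 2 * a[u, v]
                    + 4 * a[v, w]
                    + 8 * a[w, v]
                    + 16 * a[u, w]
                    + 32 * a[w, u]
                )
                t = _TRICODE_TO_TYPE[code]
                counts[t] += 1
                pair_count[v, u, t] += 1
                pair_count[v, w, t] += 1
                pair_count[u, w, t] += 1
    return TriadCensus(counts, pair_count)


def count_local_triads(
    net: DirectedNetwork, v: int, u: int, return_types: bool = False
):
    """Triad counts of all connected triples containing both ``v`` and ``u``.

    If the undirected edge (v, u) is present, any third node adjacent to
    either endpoint closes a connected triple; otherwise only common
    neighbours do.  With ``return_types`` the per-third-node triad type is
    returned as well (used by the incremental update).
    """
    if v == u:
        raise InvalidTripleError("local triad count requires two distinct nodes")
    a = net.adjacency
    und = net.undirected()
    nv = set(np.nonzero(und[v])[0].tolist())
    nu = set(np.nonzero(und[u])[0].tolist())
    s = (nv | nu) if und[v, u] else (nv & nu)
    s -= {v, u}
    local = np.zeros(16, dtype=np.int64)
    types: dict[int, int] = {}
    for w in s:
        code = (
            a[v, u]
            + 2 * a[u, v]
            + 4 * a[v, w]
            + 8 * a[w, v]
            + 16 * a[u, w]
            + 32 * a[w, u]
        )
        t = int(_TRICODE_TO_TYPE[code])
        local[t] += 1
        types[int(w)] = t
    if return_types:
        return local, types
    return local


def apply_edge_mutation(
    net: DirectedNetwork,
    census: TriadCensus,
    edge: tuple[int, int],
    add: bool,
) -> None:
    """Toggle one directed edge and update the census incrementally, in place.

    Only triads containing both endpoints can change, so the census delta is
    the difference between the local triad counts after and before the
    toggle — an O(Delta) computation.  The contribution table is reconciled
    for the mutated pair and for every third node whose triple changed, which
    keeps the table exact across arbitrarily long mutation sequences (the
    invariant is checked against a from-scratch recount in the tests).

    Raises ``ValueError`` when asked to add an existing edge, remove a
    missing one, add a self-loop, or exceed the in-degree cap.
    """
    v, u = edge
    if v == u:
        raise ValueError("self-loops are not allowed")
    a = net.adjacency
    if add:
        if a[v, u]:
            raise ValueError(f"edge ({v}, {u}) already present")
        if a[:, u].sum() >= net.max_regulators:
            raise ValueError(
                f"adding ({v}, {u}) would exceed the in-degree cap "
                f"of {net.max_regulators}"
            )
    elif not a[v, u]:
        raise ValueError(f"edge ({v}, {u}) not present")

    _, types_before = count_local_triads(net, v, u, return_types=True)
    a[v, u] = 1 if add else 0
    local_after, types_after = count_local_triads(net, v, u, return_types=True)

    pc = census.pair_count
    # census delta: triads containing {v,u} after minus before
    before_vec = np.zeros(16, dtype=np.int64)
    for t in types_before.values():
        before_vec[t] += 1
    census.counts += local_after - before_vec

    # mutated pair: full rewrite as in the local-count pass
    pc[v, u, :] = local_after
    pc[u, v, :] = 0

    # third pairs: move the single changed triple's credit between types
    for w in set(types_before) | set(types_after):
        tb = types_before.get(w)
        ta = types_after.get(w)
        if tb == ta:
            continue
        for x in (v, u):
            if tb is not None:
                if pc[x, w, tb] > 0:
                    pc[x, w, tb] -= 1
                else:
                    pc[w, x, tb] -= 1
            if ta is not None:
                lo, hi = (x, w) if x < w else (w, x)
                pc[lo, hi, ta] += 1


def compute_topology_features(net: DirectedNetwork) -> TopologyFeatures:
    """Extract the four topological feature components of a network.

    The degree histograms are probability masses over degrees 0..10; the
    out-degree folds everything above 10 into the last bin (the in-degree is
    already capped).  The census is normalised by the total number of
    connected triads; a triad-free network (including any n < 3 network)
    yields the all-zero census vector.
    """
    census = count_triads(net) if net.n >= 3 else TriadCensus(
        np.zeros(16, dtype=np.int64), np.zeros((net.n, net.n, 16), dtype=np.int64)
    )
    return features_from_state(net, census)


def features_from_state(net: DirectedNetwork, census: TriadCensus) -> TopologyFeatures:
    """Assemble TopologyFeatures from a network and its precomputed census."""
    n = net.n
    in_hist = np.bincount(
        np.minimum(net.in_degrees(), DEGREE_CAP), minlength=DEGREE_CAP + 1
    ) / n
    out_hist = np.bincount(
        np.minimum(net.out_degrees(), DEGREE_CAP), minlength=DEGREE_CAP + 1
    ) / n
    total = census.counts.sum()
    if total > 0:
        census_norm = census.counts / total
    else:
        census_norm = np.zeros(16)
    return TopologyFeatures(
        density=net.density(),
        in_hist=in_hist.astype(float),
        out_hist=out_hist.astype(float),
        census_norm=census_norm,
    )


def random_network(
    n: int,
    density: float,
    rng: np.random.Generator,
    max_regulators: int = DEFAULT_MAX_REGULATORS,
) -> DirectedNetwork:
    """Erdos–Renyi-style random candidate respecting the in-degree cap."""
    adj = (rng.random((n, n)) < density).astype(np.int8)
    np.fill_diagonal(adj, 0)
    for t in range(n):
        col = np.nonzero(adj[:, t])[0]
        if col.size > max_regulators:
            drop = rng.choice(col, size=col.size - max_regulators, replace=False)
            adj[drop, t] = 0
    return DirectedNetwork(adj, max_regulators=max_regulators)
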