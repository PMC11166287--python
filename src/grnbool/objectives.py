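"""Optimisation objectives: rank compliance (z1) and topological similarity (z2).

z1 rewards candidate networks whose edges occupy the best positions of a
regulator ranking derived from time-series data, and whose non-edges occupy
the worst.  z2 is a weighted sum of four partial losses comparing a
candidate's topology with expectations extracted from reference networks:
out-degree histogram (L1), in-degree histogram (L2), normalised triad census
(L3) — all histogram-overlap losses — and edge density (L4), a V-shaped
piecewise-linear loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netcore import DirectedNetwork, TopologyFeatures, compute_topology_features

__all__ = [
    "RankMatrix",
    "ReferenceFeatures",
    "ObjectiveWeights",
    "ObjectiveVector",
    "extract_reference_features",
    "rank_loss",
    "overlap_loss",
    "density_loss",
    "topology_loss",
    "evaluate_objectives",
]

#: Tuned partial-loss weights (out-degree, in-degree, triad census, density).
DEFAULT_ALPHAS = (0.285, 0.0604, 0.7872, 0.3377)


@dataclass
class RankMatrix:
    """Total order over ordered gene pairs as candidate regulations.

    ``ranks[r, t]`` is the rank of "r regulates t"; rank 1 is the strongest
    evidence.  Self-pairs are excluded: off-diagonal entries form a
    permutation of ``1..n(n-1)`` and the diagonal is 0.
    """

    ranks: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.ranks, dtype=np.int64)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("ranks must be a square matrix")
        n = r.shape[0]
        if np.any(np.diag(r) != 0):
            raise ValueError("self-pairs must carry rank 0 (excluded)")
        off = r[~np.eye(n, dtype=bool)]
        if sorted(off.tolist()) != list(range(1, n * n - n + 1)):
            raise ValueError("off-diagonal ranks must be a permutation of 1..n(n-1)")
        self.ranks = r

    @property
    def n(self) -> int:
        return self.ranks.shape[0]

    @property
    def n_pairs(self) -> int:
        n = self.n
        return n * (n - 1)


@dataclass
class ReferenceFeatures:
    """Expected topological properties averaged over reference networks."""

    expected_density: float
    expected_in_hist: np.ndarray
    expected_out_hist: np.ndarray
    expected_census: np.ndarray
    source_count: int


@dataclass
class ObjectiveWeights:
    """Weights of the four partial topological losses, each in [0, 1]."""

    alpha1: float = DEFAULT_ALPHAS[0]
    alpha2: float = DEFAULT_ALPHAS[1]
    alpha3: float = DEFAULT_ALPHAS[2]
    alpha4: float = DEFAULT_ALPHAS[3]

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "alpha4"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name}={val} outside [0, 1]")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.alpha1, self.alpha2, self.alpha3, self.alpha4)


@dataclass(frozen=True)
class ObjectiveVector:
    z1: float
    z2: float

    def dominates(self, other: "ObjectiveVector") -> bool:
        """Pareto dominance: no worse in both objectives, better in one."""
        return (
            self.z1 <= other.z1
            and self.z2 <= other.z2
            and (self.z1 < other.z1 or self.z2 < other.z2)
        )


def extract_reference_features(refs: list[DirectedNetwork]) -> ReferenceFeatures:
    """Average the topological features of the reference networks.

    Each reference contributes its own normalised feature set with equal
    weight, so references of different sizes mix on the probability scale
    rather than on raw counts.
    """
    if not refs:
        raise ValueError(
            "at least one reference network is required; the topological "
            "objective is undefined without references"
        )
    feats = [compute_topology_features(r) for r in refs]
    return ReferenceFeatures(
        expected_density=float(np.mean([f.density for f in feats])),
        expected_in_hist=np.mean([f.in_hist for f in feats], axis=0),
        expected_out_hist=np.mean([f.out_hist for f in feats], axis=0),
        expected_census=np.mean([f.census_norm for f in feats], axis=0),
        source_count=len(refs),
    )


def rank_loss(net: DirectedNetwork, ranks: RankMatrix) -> float:
    """Rank-compliance loss z1.

    The edge term sums the ranks of the candidate's regulations, normalised
    by the best achievable sum (the |E| smallest ranks); the non-edge term
    sums the ranks of its non-regulations, normalised by the worst achievable
    sum (the |E^C| largest ranks).  z1 = edge_term - nonedge_term is >= 0 and
    reaches 0 exactly when edges occupy the top-|E| ranks.
    """
    if net.n != ranks.n:
        raise ValueError("rank matrix size does not match the network")
    n = net.n
    off = ~np.eye(n, dtype=bool)
    edge_mask = net.adjacency.astype(bool) & off
    nonedge_mask = off & ~edge_mask
    p = ranks.n_pairs
    ne = int(edge_mask.sum())
    nc = p - ne
    if ne == 0:
        term1 = 0.0
    else:
        best = ne * (ne + 1) / 2.0  # 1 + 2 + ... + |E|
        term1 = float(ranks.ranks[edge_mask].sum()) / best
    if nc == 0:
        term2 = 1.0
    else:
        worst = nc * (2 * p - nc + 1) / 2.0  # (P-|Ec|+1) + ... + P
        term2 = float(ranks.ranks[nonedge_mask].sum()) / worst
    return term1 - term2


def overlap_loss(observed: np.ndarray, expected: np.ndarray) -> float:
    """Histogram-overlap loss: 1 - sum_i min(observed_i, expected_i)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("histograms must have equal length")
    if (observed < 0).any() or (expected < 0).any():
        raise ValueError("histograms must be non-negative")
    return float(1.0 - np.minimum(observed, expected).sum())


def density_loss(observed: float, expected: float) -> float:
    """V-shaped density loss with slope 1/x below and 1/(1-x) above x.

    Zero at observed == expected; for sparse expectations (x < 1/2) the
    right branch is flatter, slightly favouring networks denser than
    expected.
    """
    if not 0.0 < expected < 1.0:
        raise ValueError("expected density must lie strictly in (0, 1)")
    if not 0.0 <= observed <= 1.0:
        raise ValueError("observed density must lie in [0, 1]")
    if observed < expected:
        return (expected - observed) / expected
    return (observed - expected) / (1.0 - expected)


def topology_loss(
    features: TopologyFeatures,
    ref: ReferenceFeatures,
    weights: ObjectiveWeights | None = None,
) -> float:
    """Weighted topological loss z2 = a1 L1 + a2 L2 + a3 L3 + a4 L4."""
    w = weights or ObjectiveWeights()
    l1 = overlap_loss(features.out_hist, ref.expected_out_hist)
    l2 = overlap_loss(features.in_hist, ref.expected_in_hist)
    l3 = overlap_loss(features.census_norm, ref.expected_census)
    l4 = density_loss(features.density, ref.expected_density)
    return w.alpha1 * l1 + w.alpha2 * l2 + w.alpha3 * l3 + w.alpha4 * l4


def evaluate_objectives(
    net: DirectedNetwork,
    ranks: RankMatrix,
    ref: ReferenceFeatures,
    weights: ObjectiveWeights | None = None,
    features: TopologyFeatures | None = None,
) -> ObjectiveVector:
    """Evaluate (z1, z2) for a candidate network.

    ``features`` may be supplied when the caller maintains them
    incrementally; otherwise they are recomputed from scratch.
    """
    if features is None:
        features = compute_topology_features(net)
    return ObjectiveVector(
        z1=rank_loss(net, ranks),
        z2=topology_loss(features, ref, weights),
    )
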