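"""NSGA-II search over candidate influence graphs.

Each individual is a directed network (the genotype is its adjacency
matrix).  Variation operators are tailored to the problem: crossover swaps
whole regulator sets (adjacency-matrix columns) between two parents, and
mutation toggles a single random edge, which lets the topological features
be maintained incrementally instead of recomputed.  Selection is canonical
NSGA-II: fast non-dominated sorting, crowding distance, binary tournaments
and elitist (mu + lambda) truncation.

Mutating a single edge is deliberate: a bitwise flip operator with per-entry
probability p drives the expected edge count a_k of any network to n^2/2
(the recurrence a_k = a_{k-1}(1-2p) + p n^2 has fixed point n^2/2), erasing
the sparsity of realistic regulatory networks, whereas a single toggle moves
the density by at most 1/n^2 per step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .netcore import (
    DEFAULT_MAX_REGULATORS,
    DirectedNetwork,
    TopologyFeatures,
    TriadCensus,
    apply_edge_mutation,
    count_triads,
    features_from_state,
)
from .objectives import (
    ObjectiveVector,
    ObjectiveWeights,
    RankMatrix,
    ReferenceFeatures,
    rank_loss,
    topology_loss,
)

__all__ = [
    "GAConfig",
    "Individual",
    "flip_mutation_densities",
    "initial_population",
    "crossover",
    "mutate",
    "non_dominated_sort",
    "crowding_distance",
    "select_next_generation",
    "evolve",
]


@dataclass
class GAConfig:
    """Evolutionary-search settings.

    Defaults mirror the published protocol: 10 generations; the in-degree
    cap of 10 regulators.  ``population_size`` defaults to 1000 as in the
    benchmark runs; smaller values are appropriate for small networks.
    ``init_mode`` chooses how the initial population is built: "density"
    thresholds the ranking at the expected edge count, "indegree" samples
    per-gene regulator counts from the expected in-degree distribution, and
    "reference_exact" copies name-matched reference networks.
    """

    generations: int = 10
    population_size: int = 1000
    max_regulators: int = DEFAULT_MAX_REGULATORS
    crossover_prob: float = 0.9
    mutation_prob: float = 1.0
    seed: int = 0
    init_mode: str = "density"
    init_mutations: int = 5  # diversify each initial subject by 0..this many toggles

    def __post_init__(self) -> None:
        if self.generations < 0 or self.population_size <= 0:
            raise ValueError("generations and population_size must be positive")
        for p in (self.crossover_prob, self.mutation_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.init_mode not in ("density", "indegree", "reference_exact"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class Individual:
    """A candidate network with its incrementally maintained state."""

    net: DirectedNetwork
    census: TriadCensus
    features: TopologyFeatures
    objectives: ObjectiveVector | None = None
    rank: int = -1  # Pareto front index after sorting
    crowding: float = 0.0

    @classmethod
    def from_network(cls, net: DirectedNetwork) -> "Individual":
        census = count_triads(net)
        return cls(net=net, census=census, features=features_from_state(net, census))

    def refresh_features(self) -> None:
        self.features = features_from_state(self.net, self.census)
        self.objectives = None

    def evaluate(
        self,
        ranks: RankMatrix,
        ref: ReferenceFeatures,
        weights: ObjectiveWeights,
    ) -> ObjectiveVector:
        if self.objectives is None:
            self.objectives = ObjectiveVector(
                z1=rank_loss(self.net, ranks),
                z2=topology_loss(self.features, ref, weights),
            )
        return self.objectives


def flip_mutation_densities(a0: float, p: float, n: int, steps: int) -> np.ndarray:
    """Expected edge counts under a per-entry flip mutation, a_k = a_{k-1}(1-2p) + p n^2.

    Provided for analysis only: the iteration converges to n^2/2 for any
    start and any p in (0, 1), which is why the search uses single-edge
    toggles instead.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("flip probability must lie in (0, 1)")
    out = np.empty(steps + 1)
    out[0] = a0
    for k in range(1, steps + 1):
        out[k] = out[k - 1] * (1.0 - 2.0 * p) + p * n**2
    return out


def _random_toggle(ind: Individual, rng: np.random.Generator) -> None:
    """One add-or-remove edge toggle honouring the in-degree cap (in place)."""
    net = ind.net
    n = net.n
    add = bool(rng.integers(2))
    a = net.adjacency
    off = ~np.eye(n, dtype=bool)
    if add:
        candidates = np.flatnonzero((a == 0) & off)
    else:
        candidates = np.flatnonzero(a == 1)
    if candidates.size == 0:
        return
    flat = int(rng.choice(candidates))
    v, u = divmod(flat, n)
    if add and a[:, u].sum() >= net.max_regulators:
        return  # the add would break the cap: mutation is reverted (a no-op)
    apply_edge_mutation(net, ind.census, (v, u), add)
    ind.refresh_features()


def initial_population(
    ranks: RankMatrix | None,
    ref: ReferenceFeatures,
    cfg: GAConfig,
    rng: np.random.Generator,
    refs_exact: list[DirectedNetwork] | None = None,
    gene_names: list[str] | None = None,
) -> list[Individual]:
    """Build the initial population of candidate networks.

    density mode: the round(expected_density * n(n-1)) best-ranked pairs form
    a base network shared by all subjects, each then diversified by 0..5
    random single-edge toggles.  indegree mode: each gene independently draws
    its regulator count k from the expected in-degree histogram (capped at
    the regulator limit) and keeps its k best-ranked regulators.
    reference_exact mode: subjects are copies of name-matched reference
    networks, diversified by toggles to fill the population.
    """
    pop: list[Individual] = []
    if cfg.init_mode == "reference_exact":
        if not refs_exact:
            raise ValueError("reference_exact mode requires reference networks")
        if gene_names is not None:
            for r in refs_exact:
                if list(r.gene_names) != list(gene_names):
                    missing = sorted(set(gene_names) ^ set(r.gene_names))
                    raise ValueError(
                        "reference_exact requires exactly matching gene names; "
                        f"mismatched: {missing}"
                    )
        base_nets = [r.copy() for r in refs_exact]
        for i in range(cfg.population_size):
            net = base_nets[i % len(base_nets)].copy()
            net.max_regulators = cfg.max_regulators
            ind = Individual.from_network(net)
            if i >= len(base_nets):
                for _ in range(int(rng.integers(0, cfg.init_mutations + 1))):
                    _random_toggle(ind, rng)
            pop.append(ind)
        return pop

    if ranks is None:
        raise ValueError("density and indegree init modes require a rank matrix")
    n = ranks.n

    if cfg.init_mode == "density":
        m = int(round(ref.expected_density * n * (n - 1)))
        base = np.zeros((n, n), dtype=np.int8)
        order = np.argsort(ranks.ranks + np.eye(n, dtype=np.int64) * (n * n + 1), axis=None)
        chosen = 0
        for flat in order:
            if chosen >= m:
                break
            v, u = divmod(int(flat), n)
            if v == u:
                continue
            if base[:, u].sum() >= cfg.max_regulators:
                continue
            base[v, u] = 1
            chosen += 1
        base_net = DirectedNetwork(base, gene_names, cfg.max_regulators)
        for _ in range(cfg.population_size):
            ind = Individual.from_network(base_net.copy())
            for _ in range(int(rng.integers(0, cfg.init_mutations + 1))):
                _random_toggle(ind, rng)
            pop.append(ind)
        return pop

    # indegree mode
    hist = np.asarray(ref.expected_in_hist, dtype=float)
    hist = hist / hist.sum()
    kmax = min(cfg.max_regulators, hist.size - 1)
    for _ in range(cfg.population_size):
        adj = np.zeros((n, n), dtype=np.int8)
        for target in range(n):
            k = min(int(rng.choice(hist.size, p=hist)), kmax, n - 1)
            if k == 0:
                continue
            col_ranks = ranks.ranks[:, target].astype(float)
            col_ranks[target] = np.inf
            best = np.argsort(col_ranks)[:k]
            adj[best, target] = 1
        pop.append(
            Individual.from_network(DirectedNetwork(adj, gene_names, cfg.max_regulators))
        )
    return pop


def crossover(
    a: Individual, b: Individual, rng: np.random.Generator
) -> tuple[Individual, Individual]:
    """Exchange the regulator sets (columns) of a random gene subset.

    A uniformly chosen nonempty proper subset of columns is swapped between
    the parents' adjacency matrices; children's census and features are
    recomputed from scratch.
    """
    if list(a.net.gene_names) != list(b.net.gene_names):
        raise ValueError("crossover requires identical gene order")
    n = a.net.n
    cols = rng.random(n) < 0.5
    if not cols.any():
        cols[int(rng.integers(n))] = True
    if cols.all():
        cols[int(rng.integers(n))] = False
    child_a = a.net.adjacency.copy()
    child_b = b.net.adjacency.copy()
    child_a[:, cols], child_b[:, cols] = b.net.adjacency[:, cols], a.net.adjacency[:, cols]
    mk = lambda adj: Individual.from_network(
        DirectedNetwork(adj, list(a.net.gene_names), a.net.max_regulators)
    )
    return mk(child_a), mk(child_b)


def mutate(ind: Individual, rng: np.random.Generator) -> Individual:
    """Toggle one random edge in place (add and remove equally likely).

    An add that would push the target past the regulator cap is reverted,
    leaving the individual unchanged; removal on an edgeless network is a
    no-op.  Census and features are updated incrementally.
    """
    _random_toggle(ind, rng)
    return ind


def non_dominated_sort(objectives: list[ObjectiveVector]) -> list[list[int]]:
    """Fast non-dominated sorting; returns fronts as lists of indices."""
    npop = len(objectives)
    dominated: list[list[int]] = [[] for _ in range(npop)]
    dom_count = [0] * npop
    fronts: list[list[int]] = [[]]
    for i in range(npop):
        for j in range(i + 1, npop):
            if objectives[i].dominates(objectives[j]):
                dominated[i].append(j)
                dom_count[j] += 1
            elif objectives[j].dominates(objectives[i]):
                dominated[j].append(i)
                dom_count[i] += 1
    for i in range(npop):
        if dom_count[i] == 0:
            fronts[0].append(i)
    k = 0
    while fronts[k]:
        nxt: list[int] = []
        for i in fronts[k]:
            for j in dominated[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        fronts.append(nxt)
        k += 1
    fronts.pop()
    return fronts


def crowding_distance(objectives: list[ObjectiveVector]) -> list[float]:
    """Crowding distances within one front (sum of normalised neighbour gaps)."""
    m = len(objectives)
    if m <= 2:
        return [math.inf] * m
    dist = [0.0] * m
    for axis in ("z1", "z2"):
        vals = [getattr(o, axis) for o in objectives]
        order = sorted(range(m), key=lambda i: vals[i])
        span = vals[order[-1]] - vals[order[0]]
        dist[order[0]] = dist[order[-1]] = math.inf
        if span <= 0:
            continue
        for pos in range(1, m - 1):
            lo, hi = order[pos - 1], order[pos + 1]
            dist[order[pos]] += (vals[hi] - vals[lo]) / span
    return dist


def _assign_ranks(pop: list[Individual]) -> list[list[int]]:
    objs = [ind.objectives for ind in pop]
    fronts = non_dominated_sort(objs)
    for r, front in enumerate(fronts):
        dists = crowding_distance([objs[i] for i in front])
        for i, d in zip(front, dists):
            pop[i].rank = r
            pop[i].crowding = d
    return fronts


def select_next_generation(
    parents: list[Individual], offspring: list[Individual], size: int
) -> list[Individual]:
    """Elitist (mu + lambda) truncation by (front rank, crowding distance)."""
    combined = parents + offspring
    fronts = _assign_ranks(combined)
    selected: list[Individual] = []
    for front in fronts:
        members = [combined[i] for i in front]
        if len(selected) + len(members) <= size:
            selected.extend(members)
        else:
            members.sort(key=lambda ind: -ind.crowding)
            selected.extend(members[: size - len(selected)])
            break
    return selected


def _tournament(pop: list[Individual], rng: np.random.Generator) -> Individual:
    i, j = rng.integers(len(pop)), rng.integers(len(pop))
    a, b = pop[int(i)], pop[int(j)]
    if a.rank != b.rank:
        return a if a.rank < b.rank else b
    return a if a.crowding >= b.crowding else b


@dataclass
class EvolutionResult:
    population: list[Individual]
    first_front: list[Individual]
    trace: list[dict] = field(default_factory=list)


def evolve(
    ranks: RankMatrix | None,
    ref: ReferenceFeatures,
    cfg: GAConfig,
    weights: ObjectiveWeights | None = None,
    refs_exact: list[DirectedNetwork] | None = None,
    gene_names: list[str] | None = None,
) -> EvolutionResult:
    """Run the multi-objective search and return the final population.

    Fully reproducible for a fixed ``cfg.seed``.  The per-generation trace
    records (generation, individual, z1, z2, front) rows for Pareto-frontier
    plots.
    """
    if ranks is None:
        raise ValueError("the rank-compliance objective requires a rank matrix")
    w = weights or ObjectiveWeights()
    rng = np.random.default_rng(cfg.seed)
    pop = initial_population(ranks, ref, cfg, rng, refs_exact, gene_names)
    for ind in pop:
        ind.evaluate(ranks, ref, w)
    _assign_ranks(pop)
    trace: list[dict] = []

    def log(gen: int, current: list[Individual]) -> None:
        for idx, ind in enumerate(current):
            trace.append(
                {
                    "generation": gen,
                    "individual": idx,
                    "z1": ind.objectives.z1,
                    "z2": ind.objectives.z2,
                    "front": ind.rank,
                }
            )

    log(0, pop)
    for gen in range(1, cfg.generations + 1):
        offspring: list[Individual] = []
        while len(offspring) < cfg.population_size:
            p1, p2 = _tournament(pop, rng), _tournament(pop, rng)
            if rng.random() < cfg.crossover_prob:
                c1, c2 = crossover(p1, p2, rng)
            else:
                c1 = Individual.from_network(p1.net.copy())
                c2 = Individual.from_network(p2.net.copy())
            for child in (c1, c2):
                if rng.random() < cfg.mutation_prob:
                    mutate(child, rng)
                child.evaluate(ranks, ref, w)
                offspring.append(child)
        offspring = offspring[: cfg.population_size]
        pop = select_next_generation(pop, offspring, cfg.population_size)
        log(gen, pop)
    fronts = _assign_ranks(pop)
    first = [pop[i] for i in fronts[0]] if fronts else []
    return EvolutionResult(population=pop, first_front=first, trace=trace)
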