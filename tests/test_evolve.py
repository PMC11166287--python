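"""NSGA-II machinery and the network-specific variation operators."""

import math

import numpy as np
import pytest

from grnbool.evolve import (
    GAConfig,
    Individual,
    crossover,
    crowding_distance,
    evolve,
    flip_mutation_densities,
    initial_population,
    mutate,
    non_dominated_sort,
    select_next_generation,
)
from grnbool.netcore import (
    DirectedNetwork,
    compute_topology_features,
    random_network,
)
from grnbool.objectives import (
    ObjectiveVector,
    RankMatrix,
    extract_reference_features,
)

from conftest import net_from_edges


def make_ranks(n, rng):
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j]
    ranks = np.zeros((n, n), dtype=int)
    for r, k in enumerate(rng.permutation(len(pairs)), start=1):
        ranks[pairs[k]] = r
    return RankMatrix(ranks)


class TestFlipMutationRecurrence:
    @pytest.mark.parametrize("a0", [0, 10, 64, 100])
    @pytest.mark.parametrize("p", [0.01, 0.3, 0.5, 0.9])
    def test_converges_to_half_density(self, a0, p):
        n = 10
        traj = flip_mutation_densities(a0, p, n, steps=2000)
        assert traj[-1] == pytest.approx(n**2 / 2, rel=1e-6)

    def test_single_toggle_bounds_density_step(self, rng):
        ind = Individual.from_network(random_network(8, 0.2, rng))
        for _ in range(10):
            before = ind.features.density
            mutate(ind, rng)
            assert abs(ind.features.density - before) <= 1 / 64 + 1e-12


class TestInitialPopulation:
    def test_density_mode_without_diversification_is_uniform(self, rng):
        n = 8
        ranks = make_ranks(n, rng)
        ref = extract_reference_features([random_network(n, 0.2, rng)])
        cfg = GAConfig(population_size=10, seed=1, init_mode="density", init_mutations=0)
        pop = initial_population(ranks, ref, cfg, np.random.default_rng(1))
        base = pop[0].net.adjacency
        assert all(np.array_equal(ind.net.adjacency, base) for ind in pop)
        expected_edges = round(ref.expected_density * n * (n - 1))
        assert base.sum() == expected_edges

    def test_indegree_mode_respects_point_mass(self, rng):
        n = 7
        ranks = make_ranks(n, rng)
        ref = extract_reference_features([random_network(n, 0.2, rng)])
        ref.expected_in_hist = np.zeros(11)
        ref.expected_in_hist[2] = 1.0
        cfg = GAConfig(population_size=8, seed=2, init_mode="indegree")
        pop = initial_population(ranks, ref, cfg, np.random.default_rng(2))
        for ind in pop:
            assert (ind.net.in_degrees() == 2).all()

    def test_reference_exact_requires_matching_names(self, rng):
        ref_net = random_network(5, 0.2, rng)
        ref = extract_reference_features([ref_net])
        cfg = GAConfig(population_size=4, init_mode="reference_exact")
        with pytest.raises(ValueError, match="mismatch"):
            initial_population(
                None, ref, cfg, np.random.default_rng(0),
                refs_exact=[ref_net], gene_names=["x1", "x2", "x3", "x4", "x5"],
            )

    def test_reference_exact_copies_references(self, rng):
        ref_net = random_network(5, 0.3, rng)
        ref = extract_reference_features([ref_net])
        cfg = GAConfig(population_size=6, init_mode="reference_exact")
        pop = initial_population(
            None, ref, cfg, np.random.default_rng(0),
            refs_exact=[ref_net], gene_names=list(ref_net.gene_names),
        )
        assert len(pop) == 6
        assert np.array_equal(pop[0].net.adjacency, ref_net.adjacency)

    def test_all_modes_respect_in_degree_cap(self, rng):
        n = 12
        ranks = make_ranks(n, rng)
        dense_ref = random_network(n, 0.6, rng)
        ref = extract_reference_features([dense_ref])
        for mode in ("density", "indegree"):
            cfg = GAConfig(population_size=10, seed=3, init_mode=mode)
            pop = initial_population(ranks, ref, cfg, np.random.default_rng(3))
            for ind in pop:
                assert ind.net.in_degrees().max() <= cfg.max_regulators


class TestCrossover:
    def test_single_differing_column_swap(self, rng):
        # parents identical except for the regulators of gene 1
        a = net_from_edges(4, [(0, 1), (2, 3)])
        b = net_from_edges(4, [(3, 1), (2, 3)])
        for attempt in range(50):
            local = np.random.default_rng(attempt)
            c1, c2 = crossover(
                Individual.from_network(a.copy()), Individual.from_network(b.copy()), local
            )
            pair = {tuple(c1.net.adjacency[:, 1]), tuple(c2.net.adjacency[:, 1])}
            assert pair == {
                tuple(a.adjacency[:, 1]), tuple(b.adjacency[:, 1])
            }
            # all other columns are unchanged in both children
            for col in (0, 2, 3):
                assert tuple(c1.net.adjacency[:, col]) in (
                    tuple(a.adjacency[:, col]), tuple(b.adjacency[:, col])
                )

    def test_every_child_column_comes_from_a_parent(self, rng):
        pa = Individual.from_network(random_network(6, 0.3, rng))
        pb = Individual.from_network(random_network(6, 0.3, rng))
        for _ in range(10):
            c1, c2 = crossover(pa, pb, rng)
            for child in (c1, c2):
                for col in range(6):
                    col_t = tuple(child.net.adjacency[:, col])
                    assert col_t in (
                        tuple(pa.net.adjacency[:, col]),
                        tuple(pb.net.adjacency[:, col]),
                    )

    def test_children_features_are_fresh(self, rng):
        pa = Individual.from_network(random_network(6, 0.3, rng))
        pb = Individual.from_network(random_network(6, 0.3, rng))
        c1, _ = crossover(pa, pb, rng)
        fresh = compute_topology_features(c1.net)
        np.testing.assert_allclose(c1.features.census_norm, fresh.census_norm)

    def test_gene_order_mismatch_rejected(self, rng):
        a = Individual.from_network(random_network(4, 0.3, rng))
        other = DirectedNetwork(
            random_network(4, 0.3, rng).adjacency, gene_names=["w", "x", "y", "z"]
        )
        with pytest.raises(ValueError, match="gene order"):
            crossover(a, Individual.from_network(other), rng)


class _ForcedAdd:
    """Deterministic generator stub that always draws 'add' on a fixed edge."""

    def __init__(self, flat):
        self.flat = flat

    def integers(self, *args, **kwargs):
        return 1  # add

    def choice(self, candidates, **kwargs):
        return self.flat if self.flat in np.atleast_1d(candidates) else candidates[0]

    def random(self, *args, **kwargs):
        return 0.0


class TestMutate:
    def test_add_on_saturated_target_is_reverted(self):
        # gene 11's column already holds the 10-regulator maximum
        n = 12
        edges = [(r, 11) for r in range(10)]
        net = net_from_edges(n, edges)
        ind = Individual.from_network(net)
        before = ind.net.adjacency.copy()
        flat = 10 * n + 11  # edge (10, 11), absent, targets the full column
        mutate(ind, _ForcedAdd(flat))
        assert np.array_equal(ind.net.adjacency, before)

    def test_edge_count_changes_by_at_most_one(self, rng):
        ind = Individual.from_network(random_network(9, 0.25, rng))
        for _ in range(20):
            before = ind.net.n_edges
            mutate(ind, rng)
            assert abs(ind.net.n_edges - before) <= 1

    def test_incremental_features_match_recount(self, rng):
        ind = Individual.from_network(random_network(10, 0.25, rng))
        for _ in range(15):
            mutate(ind, rng)
            fresh = compute_topology_features(ind.net)
            assert ind.features.density == pytest.approx(fresh.density)
            np.testing.assert_allclose(ind.features.in_hist, fresh.in_hist)
            np.testing.assert_allclose(ind.features.census_norm, fresh.census_norm)


class TestNonDominatedSort:
    def test_two_front_example(self):
        objs = [ObjectiveVector(1, 2), ObjectiveVector(2, 1), ObjectiveVector(2, 2)]
        fronts = non_dominated_sort(objs)
        assert fronts == [[0, 1], [2]]

    def test_identical_vectors_share_a_front(self):
        objs = [ObjectiveVector(1, 1)] * 4
        assert non_dominated_sort(objs) == [[0, 1, 2, 3]]

    def test_strict_chain_gives_singleton_fronts(self):
        objs = [ObjectiveVector(i, i) for i in range(5)]
        assert non_dominated_sort(objs) == [[i] for i in range(5)]

    def test_fronts_partition_and_respect_dominance(self, rng):
        objs = [
            ObjectiveVector(float(z1), float(z2))
            for z1, z2 in rng.integers(0, 5, size=(30, 2))
        ]
        fronts = non_dominated_sort(objs)
        assert sorted(i for f in fronts for i in f) == list(range(30))
        for front in fronts:
            for i in front:
                for j in front:
                    assert not objs[i].dominates(objs[j])
        for k in range(1, len(fronts)):
            for j in fronts[k]:
                assert any(objs[i].dominates(objs[j]) for i in fronts[k - 1])


class TestCrowdingDistance:
    def test_small_fronts_are_all_infinite(self):
        assert crowding_distance([ObjectiveVector(1, 1)]) == [math.inf]
        assert crowding_distance(
            [ObjectiveVector(1, 2), ObjectiveVector(2, 1)]
        ) == [math.inf, math.inf]

    def test_equally_spaced_collinear_middle_point(self):
        objs = [ObjectiveVector(0, 2), ObjectiveVector(1, 1), ObjectiveVector(2, 0)]
        dist = crowding_distance(objs)
        assert dist[0] == math.inf and dist[2] == math.inf
        assert dist[1] == pytest.approx(2.0)

    def test_selection_is_elitist(self, rng):
        nets = [Individual.from_network(random_network(5, 0.3, rng)) for _ in range(8)]
        for k, ind in enumerate(nets):
            ind.objectives = ObjectiveVector(float(k % 4), float((8 - k) % 4))
        chosen = select_next_generation(nets[:4], nets[4:], size=4)
        ranks = sorted(ind.rank for ind in chosen)
        all_ranks = sorted(ind.rank for ind in nets)
        assert ranks == all_ranks[:4]


class TestEvolve:
    @pytest.fixture
    def small_problem(self, rng):
        n = 8
        refs = [random_network(n, 0.15, rng) for _ in range(3)]
        ref = extract_reference_features(refs)
        ranks = make_ranks(n, rng)
        return ranks, ref

    def test_fixed_seed_reproduces_first_front(self, small_problem):
        ranks, ref = small_problem
        cfg = GAConfig(generations=3, population_size=30, seed=11)
        r1 = evolve(ranks, ref, cfg)
        r2 = evolve(ranks, ref, cfg)
        assert len(r1.first_front) == len(r2.first_front)
        for a, b in zip(r1.first_front, r2.first_front):
            assert np.array_equal(a.net.adjacency, b.net.adjacency)

    def test_population_size_constant_and_cap_respected(self, small_problem):
        ranks, ref = small_problem
        cfg = GAConfig(generations=3, population_size=24, seed=4, max_regulators=10)
        res = evolve(ranks, ref, cfg)
        assert len(res.population) == 24
        for ind in res.population:
            assert ind.net.in_degrees().max() <= 10

    def test_best_z2_non_increasing_under_elitism(self, small_problem):
        ranks, ref = small_problem
        cfg = GAConfig(generations=6, population_size=40, seed=9)
        res = evolve(ranks, ref, cfg)
        best_by_gen = {}
        for row in res.trace:
            g = row["generation"]
            best_by_gen[g] = min(best_by_gen.get(g, math.inf), row["z2"])
        gens = sorted(best_by_gen)
        for a, b in zip(gens, gens[1:]):
            assert best_by_gen[b] <= best_by_gen[a] + 1e-12

    def test_incremental_state_matches_recount_at_end(self, small_problem):
        ranks, ref = small_problem
        cfg = GAConfig(generations=3, population_size=20, seed=6)
        res = evolve(ranks, ref, cfg)
        from grnbool.netcore import count_triads

        for ind in res.population[:5]:
            assert np.array_equal(ind.census.counts, count_triads(ind.net).counts)
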