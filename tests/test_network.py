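"""Interactome proximity, pathway overlap, perturbation simulation."""

import itertools
import math

import networkx as nx
import pytest
from hypothesis import given, strategies as st

from cytoprior.network import (
    extended_candidates,
    pathway_overlap,
    perturbation_impact,
    score_candidates,
    seed_proximity,
)
from cytoprior.types import SeedSet


def graph_from(edges):
    g = nx.Graph()
    g.add_edges_from(edges)
    return g


SEEDS = SeedSet(frozenset({"s1", "s2", "s3"}), "test")


class TestSeedProximity:
    def test_isolated_gene(self):
        g = nx.Graph()
        g.add_node("x")
        assert seed_proximity(g, "x", SEEDS) == 0.0

    def test_missing_gene(self):
        assert seed_proximity(graph_from([("a", "b")]), "zzz", SEEDS) == 0.0

    def test_no_seed_neighbors(self):
        g = graph_from([("x", "a"), ("x", "b")])
        assert seed_proximity(g, "x", SEEDS) == 0.0

    def test_star_center_three_seeds(self):
        g = graph_from([("x", "s1"), ("x", "s2"), ("x", "s3")])
        assert seed_proximity(g, "x", SEEDS) == pytest.approx(3 / math.sqrt(3))

    def test_hub_damping(self):
        edges = [("x", "s1")] + [("x", f"n{i}") for i in range(8)]
        assert seed_proximity(graph_from(edges), "x", SEEDS) == pytest.approx(1 / 3)

    def test_seed_excludes_itself(self):
        g = graph_from([("s1", "s2")])
        assert seed_proximity(g, "s1", SEEDS) == pytest.approx(1.0)  # only s2 counts

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ValueError):
            seed_proximity(graph_from([("a", "b")]), "a", SeedSet(frozenset(), "x"))


class TestPathwayOverlap:
    def test_gene_in_no_pathway(self):
        assert pathway_overlap({"P": frozenset({"a"})}, "x", SEEDS) == 0.0

    def test_half(self):
        pathways = {
            "P1": frozenset({"x", "s1"}),
            "P2": frozenset({"x", "a"}),
        }
        assert pathway_overlap(pathways, "x", SEEDS) == 0.5

    def test_all(self):
        pathways = {
            "P1": frozenset({"x", "s1"}),
            "P2": frozenset({"x", "s2", "b"}),
        }
        assert pathway_overlap(pathways, "x", SEEDS) == 1.0

    def test_seed_gene_excludes_self_matches(self):
        pathways = {"P1": frozenset({"s1", "a"})}
        assert pathway_overlap(pathways, "s1", SEEDS) == 0.0


def brute_force_impact(edges, nodes, seeds, removed):
    """Independent oracle: union-find component enumeration in pure Python."""

    def core(nodeset, edgeset):
        parent = {n: n for n in nodeset}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in edgeset:
            parent[find(a)] = find(b)
        counts = {}
        for n in nodeset:
            if n in seeds:
                counts[find(n)] = counts.get(find(n), 0) + 1
        return max(counts.values(), default=0)

    before = core(set(nodes), edges)
    if before == 0:
        return 0.0
    kept_nodes = set(nodes) - set(removed)
    kept_edges = [(a, b) for a, b in edges if a in kept_nodes and b in kept_nodes]
    if not (set(removed) & set(nodes)):
        return 0.0
    return 1.0 - core(kept_nodes, kept_edges) / before


class TestPerturbationImpact:
    def test_disjoint_removed_set(self):
        g = graph_from([("s1", "a")])
        assert perturbation_impact(g, SEEDS, {"zzz"}) == 0.0

    def test_path_graph_bridge(self):
        g = graph_from([("s1", "g"), ("g", "s2")])
        seeds = SeedSet(frozenset({"s1", "s2"}), "p")
        assert perturbation_impact(g, seeds, {"g"}) == pytest.approx(0.5)

    def test_remove_all_seeds(self):
        g = graph_from([("s1", "s2"), ("s2", "a")])
        seeds = SeedSet(frozenset({"s1", "s2"}), "p")
        assert perturbation_impact(g, seeds, {"s1", "s2"}) == pytest.approx(1.0)

    def test_no_seed_in_graph(self):
        g = graph_from([("a", "b")])
        assert perturbation_impact(g, SEEDS, {"a"}) == 0.0

    def test_matches_brute_force_small_random_graphs(self):
        # exhaustive sweep lives in the acceptance suite; spot-check here
        import numpy as np

        rng = np.random.default_rng(5)
        nodes = [f"n{i}" for i in range(7)]
        for _ in range(100):
            edges = [
                (a, b)
                for a, b in itertools.combinations(nodes, 2)
                if rng.uniform() < 0.35
            ]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            seeds = SeedSet(frozenset(rng.choice(nodes, size=3, replace=False)), "r")
            removed = set(rng.choice(nodes, size=2, replace=False))
            assert perturbation_impact(g, seeds, removed) == pytest.approx(
                brute_force_impact(edges, nodes, seeds.genes, removed), abs=1e-12
            )


@given(
    seed=st.integers(0, 5_000),
    n=st.integers(4, 10),
)
def test_superset_removal_is_monotone(seed, n):
    """removed1 <= removed2 implies impact(removed1) <= impact(removed2)."""
    import numpy as np

    rng = np.random.default_rng(seed)
    g = nx.gnp_random_graph(n, 0.4, seed=seed)
    seeds = SeedSet(frozenset(int(x) for x in rng.choice(n, size=2, replace=False)), "r")
    all_nodes = list(g.nodes)
    r2 = {int(x) for x in rng.choice(all_nodes, size=min(3, n), replace=False)}
    r1 = set(list(r2)[:1])
    assert perturbation_impact(g, seeds, r1) <= perturbation_impact(g, seeds, r2) + 1e-12


@given(seed=st.integers(0, 5_000))
def test_scores_invariant_to_node_insertion_order(seed):
    import numpy as np

    rng = np.random.default_rng(seed)
    edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "s1"), ("b", "s2")]
    g1 = nx.Graph()
    g1.add_edges_from(edges)
    order = list(edges)
    rng.shuffle(order)
    g2 = nx.Graph()
    g2.add_nodes_from(reversed(sorted(g1.nodes)))
    g2.add_edges_from(order)
    seeds = SeedSet(frozenset({"s1", "s2"}), "r")
    for gene in g1.nodes:
        assert seed_proximity(g1, gene, seeds) == seed_proximity(g2, gene, seeds)
        assert perturbation_impact(g1, seeds, {gene}) == perturbation_impact(
            g2, seeds, {gene}
        )


class TestExtendedCandidates:
    def test_isolated_prioritized_gene(self):
        g = nx.Graph()
        g.add_node("A")
        assert extended_candidates(g, {}, {"A"}) == set()

    def test_triangle(self):
        g = graph_from([("A", "B"), ("B", "C"), ("C", "A")])
        assert extended_candidates(g, None, {"A"}) == {"B", "C"}

    def test_full_node_set_excluded(self):
        g = graph_from([("A", "B"), ("B", "C")])
        assert extended_candidates(g, None, {"A", "B", "C"}) == set()

    def test_pathway_sharing(self):
        pathways = {"P": frozenset({"A", "X", "Y"})}
        assert extended_candidates(None, pathways, {"A"}) == {"X", "Y"}

    def test_empty_prioritized_rejected(self):
        with pytest.raises(ValueError):
            extended_candidates(nx.Graph(), {}, set())


def test_score_candidates_bundles_all_three(sim_small):
    planted = sorted(sim_small.planted)
    evidence = score_candidates(
        planted, sim_small.network, sim_small.pathways, sim_small.seeds
    )
    for gene in planted:
        assert evidence[gene].proximity > 0  # wired to >= 2 seeds by construction
        assert evidence[gene].pathway_overlap > 0  # disease module pathway
        assert 0.0 <= evidence[gene].perturbation_impact <= 1.0
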