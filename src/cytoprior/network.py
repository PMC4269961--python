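"""Interactome and pathway evidence for candidate ranking.

Three guilt-by-association scores against a phenotype seed-gene set, plus the
candidate extension to genes outside the imbalance:

- ``seed_proximity``: degree-damped count of direct seed neighbours,
  ``|N(g) & S'| / sqrt(deg(g))`` with the gene removed from its own seed set.
- ``pathway_overlap``: of the pathways containing the gene, the fraction that
  also contain at least one (other) seed.
- ``perturbation_impact``: simulate the pathway alteration caused by the
  mutated/deleted/duplicated genes by removing them from the graph and
  measuring how much the seed-connected core shrinks:
  ``1 - L_after / L_before`` where L is the largest number of seeds found
  together in one connected component.

Edges are undirected and unweighted; no diffusion/random-walk propagation is
performed — evidence stays local by design.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import networkx as nx

from .types import NetworkEvidence, SeedSet

logger = logging.getLogger(__name__)


def seed_proximity(network: nx.Graph, gene: str, seeds: SeedSet) -> float:
    """Degree-normalized direct-neighbour seed count; 0 for genes missing
    from the network or without edges."""
    if not seeds.genes:
        raise ValueError("seed set must be nonempty for proximity scoring")
    if gene not in network:
        logger.debug("gene %r absent from network; proximity = 0", gene)
        return 0.0
    degree = network.degree(gene)
    if degree == 0:
        return 0.0
    effective_seeds = seeds.without(gene)
    n_seed_neighbors = sum(1 for n in network.neighbors(gene) if n in effective_seeds)
    return n_seed_neighbors / math.sqrt(degree)


def pathway_overlap(
    pathways: Mapping[str, frozenset[str]], gene: str, seeds: SeedSet
) -> float:
    """Fraction of the gene's pathways that contain >= 1 other seed;
    0 for a gene belonging to no pathway."""
    effective_seeds = seeds.without(gene)
    member_of = [name for name, members in pathways.items() if gene in members]
    if not member_of:
        return 0.0
    with_seed = sum(1 for name in member_of if pathways[name] & effective_seeds)
    return with_seed / len(member_of)


def _seed_core_size(network: nx.Graph, seeds: frozenset[str]) -> int:
    """L = the largest number of seed genes co-resident in one connected
    component (0 when no seed is in the graph)."""
    present = seeds & set(network.nodes)
    if not present:
        return 0
    best = 0
    for component in nx.connected_components(network):
        best = max(best, len(component & present))
    return best


def perturbation_impact(
    network: nx.Graph, seeds: SeedSet, removed: Iterable[str]
) -> float:
    """Seed-connectivity loss caused by deleting ``removed`` nodes (and their
    incident edges): ``1 - L_after / L_before`` in [0, 1]. Removed genes that
    are themselves seeds leave the graph like any other node. Returns 0 when
    no seed is in the graph to begin with."""
    removed = set(removed)
    l_before = _seed_core_size(network, seeds.genes)
    if l_before == 0:
        return 0.0
    if not removed & set(network.nodes):
        return 0.0
    after = network.copy()
    after.remove_nodes_from(removed)
    l_after = _seed_core_size(after, seeds.genes)
    return 1.0 - l_after / l_before


def score_candidates(
    candidates: Iterable[str],
    network: nx.Graph | None,
    pathways: Mapping[str, frozenset[str]] | None,
    seeds: SeedSet,
) -> dict[str, NetworkEvidence]:
    """Compute all three evidences per candidate. ``perturbation_impact`` is
    the effect of deleting that single candidate. Missing network or pathway
    inputs yield zero evidence of that kind for every gene."""
    evidence: dict[str, NetworkEvidence] = {}
    for gene in candidates:
        ev = NetworkEvidence(gene=gene)
        if network is not None:
            ev.proximity = seed_proximity(network, gene, seeds)
            ev.perturbation_impact = perturbation_impact(network, seeds, {gene})
        if pathways is not None:
            ev.pathway_overlap = pathway_overlap(pathways, gene, seeds)
        evidence[gene] = ev
    return evidence


def extended_candidates(
    network: nx.Graph | None,
    pathways: Mapping[str, frozenset[str]] | None,
    prioritized: Iterable[str],
    max_distance: int = 1,
) -> set[str]:
    """Second-pass candidates outside the imbalance: genes within
    ``max_distance`` network hops of a prioritized gene, or sharing >= 1
    pathway with one; the prioritized set itself is excluded."""
    prioritized = set(prioritized)
    if not prioritized:
        raise ValueError("prioritized set must be nonempty for extension")
    extension: set[str] = set()
    if network is not None:
        for gene in prioritized & set(network.nodes):
            reached = nx.single_source_shortest_path_length(
                network, gene, cutoff=max_distance
            )
            extension.update(reached)
    if pathways is not None:
        for members in pathways.values():
            if members & prioritized:
                extension.update(members)
    return extension - prioritized
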