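"""Evidence fusion: rank each evidence, combine by weighted rank product,
select the final candidates.

Expression acts as a hard FILTER; network/pathway evidence acts as a RANKER
over the survivors. Per evidence, candidates get competition ranks (1 = best,
ties share the minimum rank; a gene unscorable in an evidence gets the worst
rank N). Ranks are fused as a weighted geometric mean of rank ratios,

    fused = exp( sum_e w_e * ln(rank_e / N) / sum_e w_e )  in (0, 1],

so lower is better and a gene ranked first everywhere scores 1/N. The fused
score is scale-free: it never mixes raw evidence units, only orderings.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

from .errors import ConfigurationError
from .types import EvidenceRanks, NetworkEvidence, PrioritizedGene, SpecificityScore

logger = logging.getLogger(__name__)

DEFAULT_EVIDENCES = ("specificity_z", "proximity", "pathway_overlap", "perturbation_impact")


def competition_ranks(
    candidates: Sequence[str],
    scores: Mapping[str, float | None],
    higher_is_better: bool = True,
) -> dict[str, int]:
    """Competition ("1224") ranks for one evidence. ``None`` marks an
    unscorable gene, which receives the worst rank N."""
    n = len(candidates)
    scored = [g for g in candidates if scores.get(g) is not None]
    unscorable = [g for g in candidates if scores.get(g) is None]
    if unscorable:
        logger.debug("%d candidate(s) unscorable, assigned worst rank %d", len(unscorable), n)
    sign = -1.0 if higher_is_better else 1.0
    ordered = sorted(scored, key=lambda g: (sign * float(scores[g]), g))
    ranks: dict[str, int] = {}
    for position, gene in enumerate(ordered, start=1):
        previous = ordered[position - 2] if position > 1 else None
        if previous is not None and float(scores[gene]) == float(scores[previous]):
            ranks[gene] = ranks[previous]
        else:
            ranks[gene] = position
    for gene in unscorable:
        ranks[gene] = n
    return ranks


def rank_evidence(
    candidates: Sequence[str],
    scores: Mapping[str, Mapping[str, float | None]],
    higher_is_better: Mapping[str, bool] | None = None,
) -> dict[str, EvidenceRanks]:
    """Rank every candidate in every named evidence.

    ``scores`` maps evidence name -> {gene -> score or None}; a missing or
    None score means unscorable (worst rank). All evidences are
    higher-is-better unless overridden.
    """
    if not candidates:
        raise ConfigurationError("cannot rank an empty candidate list")
    if len(set(candidates)) != len(candidates):
        raise ConfigurationError("duplicate symbols in candidate list")
    higher_is_better = dict(higher_is_better or {})
    result = {g: EvidenceRanks(gene=g) for g in candidates}
    for evidence_name, per_gene in scores.items():
        ranks = competition_ranks(
            candidates, per_gene, higher_is_better.get(evidence_name, True)
        )
        for gene in candidates:
            result[gene].ranks[evidence_name] = ranks[gene]
    return result


def fuse_ranks(
    ranks: Mapping[str, EvidenceRanks],
    weights: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Weighted geometric mean of rank ratios per gene; updates each
    EvidenceRanks.fused in place and returns {gene -> fused}."""
    n = len(ranks)
    if n == 0:
        raise ConfigurationError("no candidates to fuse")
    evidence_names = sorted(next(iter(ranks.values())).ranks)
    if weights is None:
        weights = {name: 1.0 for name in evidence_names}
    if any(w < 0 for w in weights.values()):
        raise ConfigurationError("fusion weights must be >= 0")
    total_weight = sum(weights.get(name, 0.0) for name in evidence_names)
    if total_weight <= 0:
        raise ConfigurationError("at least one evidence needs a positive weight")
    fused: dict[str, float] = {}
    for gene, er in ranks.items():
        log_sum = sum(
            weights.get(name, 0.0) * math.log(er.ranks[name] / n)
            for name in evidence_names
        )
        er.fused = math.exp(log_sum / total_weight)
        fused[gene] = er.fused
    return fused


def prioritize_genes(
    candidates: Sequence[str],
    expression_selection: set[str],
    fused: Mapping[str, float],
    top_k: int | None = None,
    fused_max: float | None = None,
    network_evidence: Mapping[str, NetworkEvidence] | None = None,
    require_network_evidence: bool = False,
    expression_scores: Mapping[str, SpecificityScore] | None = None,
) -> list[PrioritizedGene]:
    """Final selection: the expression filter is hard (a gene that failed it
    is never selected, whatever its network rank); survivors are ordered by
    fused score ascending (ties by symbol) and optionally cut at ``top_k``
    and/or ``fused_max``. With ``require_network_evidence`` a survivor also
    needs >= 1 strictly positive network/pathway evidence — the interactome
    "confirmation" of the expression-based selection."""
    if require_network_evidence and network_evidence is None:
        raise ConfigurationError(
            "require_network_evidence set but no network evidence supplied"
        )
    passers = []
    for gene in candidates:
        if gene not in expression_selection:
            continue
        if require_network_evidence:
            ev = network_evidence.get(gene)
            if ev is None or not ev.any_nonzero():
                continue
        passers.append(gene)
    passers.sort(key=lambda g: (fused.get(g, 1.0), g))
    if fused_max is not None:
        passers = [g for g in passers if fused.get(g, 1.0) <= fused_max]
    if top_k is not None:
        passers = passers[:top_k]
    selected_set = set(passers)
    out = []
    for gene in passers:
        out.append(
            PrioritizedGene(
                gene=gene,
                fused=float(fused.get(gene, 1.0)),
                selected=True,
                expression=(expression_scores or {}).get(gene),
                network=(network_evidence or {}).get(gene),
            )
        )
    # hard-filter invariant, asserted on every run
    assert all(pg.gene in expression_selection for pg in out)
    assert selected_set <= set(expression_selection)
    return out
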