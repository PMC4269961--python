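"""End-to-end orchestration: locus genes -> expression filter -> network
evidence (incl. pathway-perturbation simulation) -> rank fusion -> gene
prioritization -> optional extension pass -> CNV prioritization -> cohort
summary, in one call, producing a deterministic JSON-serializable report.

This module is the toolkit's single entry point for whole analyses; the
stage functions it wires together remain individually importable. Reports
embed a run manifest (tool version + full parameter snapshot) and are
payload-identical across reruns on identical inputs.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from . import __version__
from .cnv import prioritize_cnvs, summarize_cohort
from .errors import ConfigurationError, ValidationError
from .expression import genes_in_interval, select_locus_outliers
from .fusion import fuse_ranks, prioritize_genes, rank_evidence
from .network import extended_candidates, perturbation_impact, score_candidates
from .simulate import SimulatedData, SimulationConfig, generate_all
from .types import (
    CNVCall,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    SeedSet,
    VariantCatalogEntry,
)

logger = logging.getLogger(__name__)

EVIDENCE_NAMES = ("specificity_z", "proximity", "pathway_overlap", "perturbation_impact")


def check_chromosome_compatibility(
    annotation: Sequence[GeneAnnotation], intervals: Sequence[GenomicInterval]
) -> None:
    """Chromosome names are compared verbatim; if two nonempty inputs share
    no chromosome name at all, the files almost certainly use different
    naming conventions ("chr21" vs "21") and the run aborts rather than
    silently reporting zero overlap."""
    ann_chroms = {g.chrom for g in annotation}
    query_chroms = {iv.chrom for iv in intervals}
    if ann_chroms and query_chroms and not (ann_chroms & query_chroms):
        raise ValidationError(
            f"no chromosome name shared between annotation ({sorted(ann_chroms)[:3]}...) "
            f"and query intervals ({sorted(query_chroms)[:3]}...); "
            "check 'chr' prefix conventions"
        )


def run_all(
    annotation: Sequence[GeneAnnotation],
    expression: ExpressionMatrix,
    intervals: Sequence[GenomicInterval],
    tissues: str | Sequence[str],
    seeds: SeedSet | None = None,
    network: nx.Graph | None = None,
    pathways: Mapping[str, frozenset[str]] | None = None,
    cnv_calls: Sequence[CNVCall] | None = None,
    catalog: Sequence[VariantCatalogEntry] = (),
    roster: Sequence[str] | None = None,
    z_min: float = 2.0,
    fence_k: float = 1.5,
    weights: Mapping[str, float] | None = None,
    top_k: int | None = None,
    require_network_evidence: bool | None = None,
    benign_veto: bool = True,
    min_reciprocal_overlap: float = 0.5,
    min_frequency: float = 0.01,
    extend: bool = False,
) -> dict:
    """Run the full prioritization pipeline and return the report dict.

    ``require_network_evidence`` defaults to True whenever interactome or
    pathway input is available (the expression-based selection must then be
    confirmed by at least one positive network/pathway evidence) and to False
    otherwise; requesting it explicitly without supplying a network or
    pathways is a configuration error, raised before any compute.
    """
    has_network_inputs = network is not None or pathways is not None
    if require_network_evidence is None:
        require_network_evidence = has_network_inputs
    if require_network_evidence and not has_network_inputs:
        raise ConfigurationError(
            "require_network_evidence=True but neither network nor pathways supplied"
        )
    if has_network_inputs and seeds is None:
        raise ConfigurationError("network/pathway scoring needs a phenotype seed set")
    if isinstance(tissues, str):
        tissues = [tissues]
    check_chromosome_compatibility(annotation, intervals)

    # stage 1: locus gene content
    candidates: list[str] = []
    for interval in intervals:
        for gene in genes_in_interval(annotation, interval):
            if gene not in candidates:
                candidates.append(gene)

    # stage 2: expression filter (per-locus fences, any-tissue rule)
    expression_selection: set[str] = set()
    expression_scores: dict = {}
    for interval in intervals:
        locus_genes = genes_in_interval(annotation, interval)
        selected, scores = select_locus_outliers(
            expression, locus_genes, tissues, z_min=z_min, fence_k=fence_k
        )
        expression_selection.update(selected)
        for gene, score in scores.items():
            prev = expression_scores.get(gene)
            if prev is None or score.z > prev.z:
                expression_scores[gene] = score

    # stage 3: network / pathway evidence
    effective_seeds = seeds if seeds is not None else SeedSet(frozenset(), "none")
    net_evidence = score_candidates(candidates, network, pathways, effective_seeds) \
        if has_network_inputs else {g: None for g in candidates}

    # stage 4: rank fusion
    evidence_scores: dict[str, dict[str, float | None]] = {
        "specificity_z": {
            g: (expression_scores[g].z if g in expression_scores else None)
            for g in candidates
        }
    }
    if has_network_inputs:
        evidence_scores["proximity"] = {g: net_evidence[g].proximity for g in candidates}
        evidence_scores["pathway_overlap"] = {
            g: net_evidence[g].pathway_overlap for g in candidates
        }
        evidence_scores["perturbation_impact"] = {
            g: net_evidence[g].perturbation_impact for g in candidates
        }
    report: dict = {"report_version": 1}
    if candidates:
        ranks = rank_evidence(candidates, evidence_scores)
        fused = fuse_ranks(ranks, weights)
        for gene in expression_selection:
            if gene in ranks:
                ranks[gene].passes_expression_filter = True
    else:
        ranks, fused = {}, {}

    # stage 5: gene prioritization
    prioritized = prioritize_genes(
        candidates,
        expression_selection,
        fused,
        top_k=top_k,
        network_evidence=net_evidence if has_network_inputs else None,
        require_network_evidence=require_network_evidence,
        expression_scores=expression_scores,
    )
    selected_genes = [pg.gene for pg in prioritized]

    # stage 6: pathway-alteration simulation for the selected set as a whole
    overall_impact = None
    if network is not None and selected_genes and seeds is not None:
        overall_impact = perturbation_impact(network, seeds, set(selected_genes))

    # optional second pass: candidates outside the imbalance
    extension: list[str] = []
    if extend and selected_genes and has_network_inputs:
        extension = sorted(
            extended_candidates(network, pathways, set(selected_genes))
        )

    gene_records = []
    for gene in candidates:
        score = expression_scores.get(gene)
        ev = net_evidence.get(gene)
        gene_records.append(
            {
                "gene": gene,
                "unscorable": score is None,
                "passes_expression_filter": gene in expression_selection,
                "selected": gene in set(selected_genes),
                "specificity_z": None if score is None else score.z,
                "locus_outlier": None if score is None else score.locus_outlier,
                "target_expression": None if score is None else score.target_expression,
                "proximity": None if ev is None else ev.proximity,
                "pathway_overlap": None if ev is None else ev.pathway_overlap,
                "perturbation_impact": None if ev is None else ev.perturbation_impact,
                "ranks": dict(sorted(ranks[gene].ranks.items())) if gene in ranks else {},
                "fused": fused.get(gene),
            }
        )
    gene_records.sort(key=lambda r: (not r["selected"], r["fused"] if r["fused"] is not None else 1.0, r["gene"]))

    report.update(
        {
            "manifest": {
                "tool": "cytoprior",
                "version": __version__,
                "parameters": {
                    "z_min": z_min,
                    "fence_k": fence_k,
                    "weights": dict(weights) if weights else {n: 1.0 for n in evidence_scores},
                    "top_k": top_k,
                    "require_network_evidence": require_network_evidence,
                    "benign_veto": benign_veto,
                    "min_reciprocal_overlap": min_reciprocal_overlap,
                    "min_frequency": min_frequency,
                    "tissues": list(tissues),
                    "intervals": [
                        {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
                        for iv in intervals
                    ],
                },
            },
            "candidates": candidates,
            "selected_genes": selected_genes,
            "genes": gene_records,
            "pathway_perturbation": overall_impact,
            "extended_candidates": extension,
        }
    )

    # stage 7-8: CNV prioritization and cohort summary
    if cnv_calls is not None:
        cnv_results = prioritize_cnvs(
            cnv_calls,
            set(selected_genes),
            annotation,
            catalog,
            min_reciprocal_overlap=min_reciprocal_overlap,
            min_frequency=min_frequency,
            benign_veto=benign_veto,
        )
        cohort_roster = roster if roster is not None else sorted(
            {c.patient_id for c in cnv_calls}
        )
        summary = summarize_cohort(cnv_results, cohort_roster)
        report["cnvs"] = [
            {
                "patient_id": r.call.patient_id,
                "chrom": r.call.chrom,
                "start": r.call.start,
                "end": r.call.end,
                "dosage": r.call.dosage,
                "genes": r.genes,
                "prioritized_genes": r.prioritized_genes,
                "benign_match": r.benign_match,
                "verdict": r.verdict,
            }
            for r in cnv_results
        ]
        report["summary"] = {
            "n_patients": summary.n_patients,
            "n_cnv_prioritized_total": summary.n_cnv_prioritized_total,
            "histogram": {str(k): v for k, v in summary.histogram.items()},
            "yield_percent": summary.yield_percent,
        }
    return report


# ---------------------------------------------------------------------------
# simulation-based evaluation


def evaluate_genes(selected: set[str], planted: set[str], candidates: set[str]) -> dict:
    """Precision/recall of the selected gene set against the planted truth,
    within the candidate universe."""
    planted = planted & candidates
    tp = len(selected & planted)
    fp = len(selected - planted)
    fn = len(planted - selected)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": tp / (tp + fp) if (tp + fp) else 1.0,
        "recall": tp / (tp + fn) if (tp + fn) else 1.0,
    }


def evaluate_cnvs(cnv_records: Sequence[dict], truth: pd.DataFrame) -> dict:
    """Balanced accuracy of the prioritized/not-prioritized verdict against
    the truth table's pathogenic/benign classes."""
    key_cols = ["patient_id", "chrom", "start", "end", "dosage"]
    classes: dict[tuple, str] = {}
    for _, row in truth.iterrows():
        key = tuple(row[c] for c in key_cols)
        cls = row["cnv_class"]
        if classes.get(key, cls) != cls:
            raise ValidationError(f"conflicting truth classes for CNV {key}")
        classes[key] = cls
    tp = fn = tn = fp = 0
    for rec in cnv_records:
        key = tuple(rec[c] for c in key_cols)
        if key not in classes:
            raise ValidationError(f"CNV {key} missing from truth table")
        predicted_pathogenic = rec["verdict"] == "prioritized"
        if classes[key] == "pathogenic":
            tp += predicted_pathogenic
            fn += not predicted_pathogenic
        else:
            fp += predicted_pathogenic
            tn += not predicted_pathogenic
    sensitivity = tp / (tp + fn) if (tp + fn) else 1.0
    specificity = tn / (tn + fp) if (tn + fp) else 1.0
    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "balanced_accuracy": (sensitivity + specificity) / 2.0,
    }


def locus_interval(data: SimulatedData) -> GenomicInterval:
    """The disease-locus query interval: the span of the first chromosome."""
    locus = [g for g in data.annotation if g.chrom == data.locus_chrom]
    return GenomicInterval(data.locus_chrom, 0, max(g.end for g in locus) + 1)


def recovery_replicate(config: SimulationConfig) -> dict:
    """One simulate -> run_all -> score cycle; the unit of the
    parameter-recovery experiment."""
    data = generate_all(config)
    report = run_all(
        annotation=data.annotation,
        expression=data.expression,
        intervals=[locus_interval(data)],
        tissues=data.config.target_tissue,
        seeds=data.seeds,
        network=data.network,
        pathways=data.pathways,
        cnv_calls=data.calls,
        catalog=data.catalog,
        roster=[f"P{p:04d}" for p in range(config.n_patients)],
    )
    gene_metrics = evaluate_genes(
        set(report["selected_genes"]), set(data.planted), set(report["candidates"])
    )
    cnv_metrics = evaluate_cnvs(report["cnvs"], data.truth)
    return {
        "seed": config.seed,
        "genes": gene_metrics,
        "cnvs": cnv_metrics,
        "n_candidates": len(report["candidates"]),
        "n_selected": len(report["selected_genes"]),
        "yield_percent": report["summary"]["yield_percent"],
    }


def recovery_experiment(
    seeds: Sequence[int], base_config: SimulationConfig | None = None
) -> dict:
    """Pooled planted-gene precision/recall and CNV balanced accuracy over
    replicate simulations (one per seed)."""
    base = asdict(base_config) if base_config is not None else {}
    base.pop("seed", None)
    base["benign_freq_range"] = tuple(base.get("benign_freq_range", (0.01, 0.2)))
    replicates = [recovery_replicate(SimulationConfig(seed=s, **base)) for s in seeds]
    g_tp = sum(r["genes"]["tp"] for r in replicates)
    g_fp = sum(r["genes"]["fp"] for r in replicates)
    g_fn = sum(r["genes"]["fn"] for r in replicates)
    c_tp = sum(r["cnvs"]["tp"] for r in replicates)
    c_fn = sum(r["cnvs"]["fn"] for r in replicates)
    c_tn = sum(r["cnvs"]["tn"] for r in replicates)
    c_fp = sum(r["cnvs"]["fp"] for r in replicates)
    sens = c_tp / (c_tp + c_fn) if (c_tp + c_fn) else 1.0
    spec = c_tn / (c_tn + c_fp) if (c_tn + c_fp) else 1.0
    return {
        "n_replicates": len(replicates),
        "gene_precision": g_tp / (g_tp + g_fp) if (g_tp + g_fp) else 1.0,
        "gene_recall": g_tp / (g_tp + g_fn) if (g_tp + g_fn) else 1.0,
        "cnv_sensitivity": sens,
        "cnv_specificity": spec,
        "cnv_balanced_accuracy": (sens + spec) / 2.0,
        "mean_yield_percent": sum(r["yield_percent"] for r in replicates) / len(replicates),
        "replicates": replicates,
    }
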