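"""Synthetic-data generator with planted ground truth.

Emulates every input the toolkit consumes — gene annotation, a genes x
tissues expression matrix, a scale-free interactome with a wired-in disease
module, pathway gene sets, a patient cohort of CNV calls and a benign-variant
catalog — so that the whole pipeline is testable end-to-end without any
external database snapshot, and planted-gene recovery can be measured.

The stated world
----------------
One chromosome (the first) carries the disease locus. ``n_planted`` genes on
it are "disease genes": they get ``effect_log2fc`` extra log2 expression in
the target tissue only, on top of per-gene/tissue baselines drawn as
``log2 value ~ Normal(5, noise_sd)``; the matrix is stored on the raw scale
``2**y - 1``. Defaults mirror the scale of the worked clinical material the
method was developed on: a ~50-gene locus (the 7q36 case spans 45 genes)
with 12 planted disease genes (the trisomy-21 case selected 12 locus
outliers), a 30-tissue panel (GTEx-scale), effect +3 log2 units over noise
SD 0.5, a 205-patient cohort in which a patient carries pathogenic CNVs with
probability 181/205, each pathogenic call covering >= 1 planted gene, plus
0-5 benign calls drawn verbatim from the generated catalog.

A single global seed fans out to independent substreams (genome /
expression / network / cohort), so regenerating one component never perturbs
the others; identical config => byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from . import io as cio
from .errors import ValidationError
from .types import (
    CNVCall,
    ExpressionMatrix,
    GeneAnnotation,
    SeedSet,
    VariantCatalogEntry,
)

import pandas as pd

_SUBSTREAMS = ("genome", "expression", "network", "cohort")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the stated synthetic world (see module docstring)."""

    seed: int = 0
    n_chrom: int = 4
    genes_per_chrom: int = 50
    n_tissues: int = 30
    n_planted: int = 12
    effect_log2fc: float = 3.0
    noise_sd: float = 0.5
    baseline_log2_mean: float = 5.0
    network_size: int = 200
    attachment_m: int = 2
    n_seeds: int = 10
    n_patients: int = 205
    pathogenic_prob: float = 181.0 / 205.0
    benign_catalog_size: int = 50
    benign_freq_range: tuple[float, float] = (0.01, 0.2)
    n_distractor_pathways: int = 20
    target_tissue: str = "brain"
    max_flank_bp: int = 50_000

    def __post_init__(self) -> None:
        counts = dict(
            n_chrom=self.n_chrom,
            genes_per_chrom=self.genes_per_chrom,
            n_planted=self.n_planted,
            network_size=self.network_size,
            attachment_m=self.attachment_m,
            n_seeds=self.n_seeds,
            n_patients=self.n_patients,
            benign_catalog_size=self.benign_catalog_size,
        )
        for name, value in counts.items():
            if value < 1:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.n_tissues < 2:
            raise ValidationError("n_tissues must be >= 2 for specificity scoring")
        if not (0.0 <= self.pathogenic_prob <= 1.0):
            raise ValidationError("pathogenic_prob must be in [0, 1]")
        if self.n_planted > self.genes_per_chrom:
            raise ValidationError("n_planted cannot exceed genes on the locus chromosome")
        if self.network_size > self.n_chrom * self.genes_per_chrom:
            raise ValidationError("network_size cannot exceed the number of genes")

    def rng(self, component: str) -> np.random.Generator:
        """Deterministic per-component substream."""
        if component not in _SUBSTREAMS:
            raise ValueError(f"unknown substream {component!r}")
        root = np.random.SeedSequence(self.seed)
        child = root.spawn(len(_SUBSTREAMS))[_SUBSTREAMS.index(component)]
        return np.random.default_rng(child)

    @property
    def tissues(self) -> list[str]:
        others = [f"tissue_{i:02d}" for i in range(1, self.n_tissues)]
        return [self.target_tissue] + others


@dataclass
class SimulatedData:
    """The full bundle one config generates."""

    config: SimulationConfig
    annotation: list[GeneAnnotation]
    planted: frozenset[str]
    expression: ExpressionMatrix
    network: nx.Graph
    pathways: dict[str, frozenset[str]]
    seeds: SeedSet
    calls: list[CNVCall]
    catalog: list[VariantCatalogEntry]
    truth: pd.DataFrame = field(repr=False)

    @property
    def locus_chrom(self) -> str:
        return self.annotation[0].chrom


def generate_genome(config: SimulationConfig) -> list[GeneAnnotation]:
    """Non-overlapping genes laid left-to-right on each chromosome.

    Gene lengths ~ U[5kb, 50kb], intergenic gaps ~ U[1kb, 100kb].
    """
    rng = config.rng("genome")
    records: list[GeneAnnotation] = []
    gene_id = 0
    for c in range(1, config.n_chrom + 1):
        cursor = int(rng.integers(1_000, 100_001))
        for _ in range(config.genes_per_chrom):
            length = int(rng.integers(5_000, 50_001))
            records.append(
                GeneAnnotation(f"chr{c}", cursor, cursor + length, f"G{gene_id:04d}")
            )
            gene_id += 1
            cursor += length + int(rng.integers(1_000, 100_001))
    return records


def choose_planted(
    config: SimulationConfig, annotation: Sequence[GeneAnnotation]
) -> frozenset[str]:
    """Disease genes: ``n_planted`` genes drawn from the locus chromosome
    (the first chromosome of the annotation)."""
    locus_chrom = annotation[0].chrom
    locus_genes = [g.symbol for g in annotation if g.chrom == locus_chrom]
    rng = config.rng("genome")
    rng.integers(0, 1 << 30)  # advance past the layout draw domain
    picked = rng.choice(len(locus_genes), size=config.n_planted, replace=False)
    return frozenset(locus_genes[i] for i in sorted(picked))


def generate_expression(
    config: SimulationConfig,
    annotation: Sequence[GeneAnnotation],
    planted: frozenset[str],
    target_tissue: str | None = None,
) -> ExpressionMatrix:
    """Baseline log2 values ~ N(baseline_log2_mean, noise_sd) per gene/tissue;
    planted genes get ``effect_log2fc`` added in the target tissue only.
    Stored on the raw scale 2**y - 1, floored at 0."""
    target_tissue = target_tissue or config.target_tissue
    tissues = config.tissues
    if target_tissue not in tissues:
        raise ValidationError(f"target tissue {target_tissue!r} not in tissue panel")
    rng = config.rng("expression")
    genes = [g.symbol for g in annotation]
    y = rng.normal(config.baseline_log2_mean, config.noise_sd, size=(len(genes), len(tissues)))
    t_idx = tissues.index(target_tissue)
    for i, gene in enumerate(genes):
        if gene in planted:
            y[i, t_idx] += config.effect_log2fc
    raw = np.maximum(np.exp2(y) - 1.0, 0.0)
    return ExpressionMatrix(pd.DataFrame(raw, index=genes, columns=tissues))


def generate_network_and_pathways(
    config: SimulationConfig,
    annotation: Sequence[GeneAnnotation],
    planted: frozenset[str],
) -> tuple[nx.Graph, dict[str, frozenset[str]], SeedSet]:
    """Scale-free interactome with a planted disease module.

    A preferential-attachment graph over ``network_size`` genes; ``n_seeds``
    phenotype seed genes are drawn from chromosomes other than the locus
    (known disease genes outside the imbalance); every planted gene is wired
    to >= 2 seeds; one pathway holds seeds + planted genes, plus
    ``n_distractor_pathways`` pathways of random genes.
    """
    rng = config.rng("network")
    genes = [g.symbol for g in annotation][: config.network_size]
    locus_chrom = annotation[0].chrom
    graph_seed = int(rng.integers(0, 2**31 - 1))
    graph = nx.barabasi_albert_graph(len(genes), config.attachment_m, seed=graph_seed)
    graph = nx.relabel_nodes(graph, dict(enumerate(genes)))

    off_locus = [
        g.symbol
        for g in annotation
        if g.chrom != locus_chrom and g.symbol in graph and g.symbol not in planted
    ]
    if len(off_locus) < config.n_seeds:
        raise ValidationError("not enough off-locus genes to draw the seed set")
    seed_idx = rng.choice(len(off_locus), size=config.n_seeds, replace=False)
    seed_genes = frozenset(off_locus[i] for i in sorted(seed_idx))
    seeds = SeedSet(genes=seed_genes, label="synthetic-phenotype")

    seed_list = sorted(seed_genes)
    for gene in sorted(planted):
        partners = rng.choice(len(seed_list), size=2, replace=False)
        for j in partners:
            graph.add_edge(gene, seed_list[int(j)])

    pathways: dict[str, frozenset[str]] = {
        "disease_module": frozenset(seed_genes | planted)
    }
    all_genes = [g.symbol for g in annotation]
    for p in range(config.n_distractor_pathways):
        size = min(int(rng.integers(10, 31)), len(all_genes))
        members = rng.choice(len(all_genes), size=size, replace=False)
        pathways[f"pathway_{p:03d}"] = frozenset(all_genes[i] for i in sorted(members))
    return graph, pathways, seeds


def generate_cohort(
    config: SimulationConfig,
    annotation: Sequence[GeneAnnotation],
    planted: frozenset[str],
) -> tuple[list[CNVCall], list[VariantCatalogEntry], pd.DataFrame]:
    """Patient CNV calls, benign catalog, and the per-CNV truth table.

    Each patient is a pathogenic carrier with probability ``pathogenic_prob``
    and then receives 1-3 pathogenic CNVs, each spanning one planted gene
    with random flanks up to ``max_flank_bp``; every patient additionally
    receives 0-5 benign CNVs copied from catalog entries. Catalog intervals
    are rejected if they come within ``max_flank_bp`` of a planted gene, so
    benign and pathogenic classes cannot collide by construction (common
    variants are depleted around dosage-sensitive disease genes).
    """
    rng = config.rng("cohort")
    by_symbol = {g.symbol: g for g in annotation}
    planted_list = sorted(planted)
    chrom_span: dict[str, int] = {}
    for g in annotation:
        chrom_span[g.chrom] = max(chrom_span.get(g.chrom, 0), g.end)

    margin = config.max_flank_bp
    planted_by_chrom: dict[str, list[GeneAnnotation]] = {}
    for s in planted_list:
        planted_by_chrom.setdefault(by_symbol[s].chrom, []).append(by_symbol[s])

    lo, hi = config.benign_freq_range
    catalog: list[VariantCatalogEntry] = []
    chroms = sorted(chrom_span)
    while len(catalog) < config.benign_catalog_size:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        length = int(rng.integers(20_000, 200_001))
        start = int(rng.integers(0, max(chrom_span[chrom] - length, 1)))
        end = start + length
        near_planted = any(
            start < g.end + margin and end > g.start - margin
            for g in planted_by_chrom.get(chrom, [])
        )
        if near_planted:
            continue
        freq = float(rng.uniform(lo, hi))
        catalog.append(VariantCatalogEntry(chrom, start, end, freq))
    catalog.sort(key=lambda e: (e.chrom, e.start, e.end))

    calls: list[CNVCall] = []
    truth_rows: list[dict] = []
    for p in range(config.n_patients):
        pid = f"P{p:04d}"
        if rng.uniform() < config.pathogenic_prob:
            n_path = int(rng.integers(1, 4))
            for _ in range(n_path):
                gene = by_symbol[planted_list[int(rng.integers(0, len(planted_list)))]]
                fl = int(rng.integers(1_000, config.max_flank_bp + 1))
                fr = int(rng.integers(1_000, config.max_flank_bp + 1))
                dosage = "gain" if rng.uniform() < 0.5 else "loss"
                call = CNVCall(pid, gene.chrom, max(gene.start - fl, 0), gene.end + fr, dosage)
                calls.append(call)
                truth_rows.append(_truth_row(call, "pathogenic"))
        n_benign = int(rng.integers(0, 6))
        for _ in range(n_benign):
            entry = catalog[int(rng.integers(0, len(catalog)))]
            dosage = "gain" if rng.uniform() < 0.5 else "loss"
            call = CNVCall(pid, entry.chrom, entry.start, entry.end, dosage)
            calls.append(call)
            truth_rows.append(_truth_row(call, "benign"))

    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "chrom", "start", "end", "dosage", "cnv_class"]
    ).drop_duplicates()
    return calls, catalog, truth


def _truth_row(call: CNVCall, cnv_class: str) -> dict:
    return {
        "patient_id": call.patient_id,
        "chrom": call.chrom,
        "start": call.start,
        "end": call.end,
        "dosage": call.dosage,
        "cnv_class": cnv_class,
    }


def generate_all(config: SimulationConfig) -> SimulatedData:
    """Generate the complete bundle for one config."""
    annotation = generate_genome(config)
    planted = choose_planted(config, annotation)
    expression = generate_expression(config, annotation, planted)
    network, pathways, seeds = generate_network_and_pathways(config, annotation, planted)
    calls, catalog, truth = generate_cohort(config, annotation, planted)
    return SimulatedData(
        config=config,
        annotation=annotation,
        planted=planted,
        expression=expression,
        network=network,
        pathways=pathways,
        seeds=seeds,
        calls=calls,
        catalog=catalog,
        truth=truth,
    )


def write_fixtures(data: SimulatedData, out_dir: str | Path) -> dict[str, Path]:
    """Write every standard-format file plus the truth table and config."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": out / "annotation.bed",
        "expression": out / "expression.tsv",
        "network": out / "network.tsv",
        "pathways": out / "pathways.gmt",
        "seeds": out / "seeds.txt",
        "cnv_calls": out / "cnv_calls.tsv",
        "catalog": out / "benign_catalog.tsv",
        "truth": out / "truth.tsv",
        "planted": out / "planted_genes.txt",
        "config": out / "config.json",
    }
    cio.write_gene_annotation(data.annotation, paths["annotation"])
    cio.write_expression_matrix(data.expression, paths["expression"])
    cio.write_network(data.network, paths["network"])
    cio.write_genesets_gmt(data.pathways, paths["pathways"])
    paths["seeds"].write_text("".join(f"{g}\n" for g in sorted(data.seeds.genes)))
    cio.write_cnv_calls(data.calls, paths["cnv_calls"])
    cio.write_variant_catalog(data.catalog, paths["catalog"])
    data.truth.sort_values(list(data.truth.columns)).to_csv(
        paths["truth"], sep="\t", index=False
    )
    paths["planted"].write_text("".join(f"{g}\n" for g in sorted(data.planted)))
    cio.write_report(asdict(data.config), paths["config"], format="json")
    return paths
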