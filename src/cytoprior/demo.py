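"""Synthetic worked-case fixture: a terminal-7q deletion locus.

This is a SYNTHETIC stand-in, not real data: a 45-gene region of chromosome 7
(~152-158 Mb, the 7q36.2-q36.3 band) shaped so that exactly two genes —
LIMBR1 and MNX1, the candidates for lumbosacral dysgenesis — are expressed
more abundantly in the affected tissue and are wired to the phenotype seed
genes. The real analysis needs external expression/interactome snapshots;
this fixture exercises the rule plumbing end to end with a known answer.

Baseline genes have per-gene constant expression across tissues (robust
z exactly 0), so only the two elevated genes can pass either arm of the
outlier rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GeneAnnotation, GenomicInterval, SeedSet

LOCUS = GenomicInterval("chr7", 152_000_000, 158_000_000)
CANDIDATE_GENES = ("LIMBR1", "MNX1")
TARGET_TISSUE = "spinal cord"
_TISSUES = ("spinal cord", "liver", "kidney", "lung", "blood")
_SEEDS = ("SHH", "GLI3", "CDX2", "TBXT")


@dataclass
class LocusDemo:
    annotation: list[GeneAnnotation]
    expression: ExpressionMatrix
    network: nx.Graph
    pathways: dict[str, frozenset[str]]
    seeds: SeedSet
    interval: GenomicInterval
    target_tissue: str


def sacral_locus_demo(n_genes: int = 45) -> LocusDemo:
    """Build the synthetic 45-gene 7q36-like fixture (see module docstring)."""
    span = len(LOCUS) // n_genes
    annotation: list[GeneAnnotation] = []
    planted_positions = {n_genes // 3: "LIMBR1", (2 * n_genes) // 3: "MNX1"}
    for i in range(n_genes):
        symbol = planted_positions.get(i, f"SEG7Q{i:03d}")
        start = LOCUS.start + i * span + 10_000
        annotation.append(GeneAnnotation("chr7", start, start + span - 20_000, symbol))

    # per-gene constant baselines (z = 0); deterministic spread keeps IQR > 0
    rows = {}
    for i, g in enumerate(annotation):
        base = 50.0 + 100.0 * ((i * 37) % n_genes) / n_genes
        values = np.full(len(_TISSUES), base)
        if g.symbol in CANDIDATE_GENES:
            values = values.copy()
            values[0] = base * 40.0  # elevated in the affected tissue only
        rows[g.symbol] = values
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(_TISSUES))
    expression = ExpressionMatrix(frame)

    network = nx.Graph()
    network.add_edge("LIMBR1", "SHH")
    network.add_edge("LIMBR1", "GLI3")
    network.add_edge("MNX1", "CDX2")
    network.add_edge("MNX1", "TBXT")
    network.add_edge("SHH", "GLI3")
    network.add_edge("SEG7Q010", "SEG7Q011")  # background edge without seeds

    pathways = {
        "caudal_development": frozenset(_SEEDS) | frozenset(CANDIDATE_GENES),
        "housekeeping": frozenset({"SEG7Q005", "SEG7Q006", "SEG7Q007"}),
    }
    seeds = SeedSet(genes=frozenset(_SEEDS), label="lumbosacral dysgenesis")
    return LocusDemo(
        annotation=annotation,
        expression=expression,
        network=network,
        pathways=pathways,
        seeds=seeds,
        interval=LOCUS,
        target_tissue=TARGET_TISSUE,
    )
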