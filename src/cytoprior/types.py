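"""Core domain types.

Coordinates are 0-based, half-open (BED convention) throughout. Gene identity
is plain symbol-string equality; no alias resolution is attempted. Chromosome
names are taken verbatim from input files — "chr21" and "21" are different
chromosomes and mixing conventions across files is reported as an error at
pipeline level rather than producing silent non-overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

DOSAGE_TOKENS = ("gain", "loss")


@dataclass(frozen=True, order=True)
class GeneAnnotation:
    """One gene interval: ``[start, end)`` on ``chrom``, named by ``symbol``."""

    chrom: str
    start: int
    end: int
    symbol: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chromosome name must be nonempty")
        if not self.symbol:
            raise ValidationError("gene symbol must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval for {self.symbol}: "
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicInterval:
    """A query interval (a chromosome imbalance or CNV footprint)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval on {self.chrom}: [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CNVCall:
    """A patient-level copy-number segment (array-CGH style call)."""

    patient_id: str
    chrom: str
    start: int
    end: int
    dosage: str  # "gain" | "loss"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid CNV for {self.patient_id}: [{self.start}, {self.end})"
            )
        if self.dosage not in DOSAGE_TOKENS:
            raise ValidationError(
                f"unknown dosage token {self.dosage!r}; expected one of {DOSAGE_TOKENS}"
            )

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


@dataclass(frozen=True)
class VariantCatalogEntry:
    """A benign-catalog record: an interval seen in healthy populations at
    the given population frequency (DGV-like)."""

    chrom: str
    start: int
    end: int
    frequency: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid catalog interval on {self.chrom}: [{self.start}, {self.end})"
            )
        if not (0.0 <= self.frequency <= 1.0):
            raise ValidationError(
                f"catalog frequency must be in [0, 1], got {self.frequency}"
            )


class ExpressionMatrix:
    """Genes x tissues nonnegative expression values.

    Thin wrapper over a pandas DataFrame (genes as index, tissues as columns)
    that enforces the container invariants once at construction: no negative
    values, no duplicate gene or tissue names. Units are not assumed (raw
    intensities or TPM-like are both fine); all downstream scoring works on
    log2(x + 1).
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene symbol in expression matrix: {dup!r}")
        if values.columns.has_duplicates:
            dup = values.columns[values.columns.duplicated()][0]
            raise ValidationError(f"duplicate tissue name in expression matrix: {dup!r}")
        arr = values.to_numpy(dtype=float)
        if arr.size and (np.isnan(arr).any() or (arr < 0).any()):
            raise ValidationError("expression values must be finite and nonnegative")
        self._df = values.astype(float)

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    @property
    def genes(self) -> list[str]:
        return [str(g) for g in self._df.index]

    @property
    def tissues(self) -> list[str]:
        return [str(t) for t in self._df.columns]

    @property
    def n_tissues(self) -> int:
        return self._df.shape[1]

    def __contains__(self, gene: str) -> bool:
        return gene in self._df.index

    def row(self, gene: str) -> np.ndarray:
        """Raw-scale values across tissues for one gene."""
        if gene not in self._df.index:
            raise KeyError(f"gene {gene!r} not in expression matrix")
        return self._df.loc[gene].to_numpy(dtype=float)

    def log_row(self, gene: str) -> np.ndarray:
        """log2(x + 1) values across tissues for one gene."""
        return np.log2(self.row(gene) + 1.0)

    def log_value(self, gene: str, tissue: str) -> float:
        if tissue not in self._df.columns:
            raise KeyError(f"tissue {tissue!r} not in expression matrix")
        return float(np.log2(float(self._df.at[gene, tissue]) + 1.0))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ExpressionMatrix) and self._df.equals(other._df)

    def __repr__(self) -> str:
        return f"ExpressionMatrix({len(self.genes)} genes x {self.n_tissues} tissues)"


@dataclass(frozen=True)
class SeedSet:
    """Phenotype seed genes: the known disease/trait genes that anchor
    guilt-by-association scoring."""

    genes: frozenset[str]
    label: str = "phenotype"

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))

    def without(self, gene: str) -> frozenset[str]:
        """Seeds excluding ``gene`` itself (self-matches never count)."""
        return self.genes - {gene}


@dataclass
class SpecificityScore:
    """Expression evidence for one gene in one target tissue.

    ``z`` is the robust cross-tissue z-score of the log2 target-tissue value;
    ``locus_outlier`` flags a value above the Tukey upper fence computed over
    the locus genes; ``target_expression`` is the log2(x+1) target value.
    """

    gene: str
    tissue: str
    z: float
    locus_outlier: bool
    target_expression: float


@dataclass
class NetworkEvidence:
    """Interactome/pathway evidence for one candidate gene."""

    gene: str
    proximity: float = 0.0
    pathway_overlap: float = 0.0
    perturbation_impact: float = 0.0

    def any_nonzero(self) -> bool:
        return (
            self.proximity > 0
            or self.pathway_overlap > 0
            or self.perturbation_impact > 0
        )


@dataclass
class EvidenceRanks:
    """Per-gene competition ranks (1 = best, ties share the minimum rank)
    across named evidences, plus the fused rank-product score in (0, 1]."""

    gene: str
    ranks: dict[str, int] = field(default_factory=dict)
    fused: float = 1.0
    passes_expression_filter: bool = False


@dataclass
class PrioritizedGene:
    gene: str
    fused: float
    selected: bool
    expression: SpecificityScore | None = None
    network: NetworkEvidence | None = None
    ranks: dict[str, int] = field(default_factory=dict)


@dataclass
class PrioritizedCNV:
    """A CNV call with its gene content and prioritization verdict.

    verdict: "prioritized" iff it holds >= 1 prioritized gene and does not
    match the benign catalog; "benign" iff it matches the catalog;
    "unranked" otherwise.
    """

    call: CNVCall
    genes: list[str]
    prioritized_genes: list[str]
    benign_match: bool
    verdict: str

    def __post_init__(self) -> None:
        # "benign" is only assignable on a catalog match, "prioritized" only
        # with gene support, "unranked" only without it; whether a catalog
        # match vetoes prioritization is the caller's (configurable) policy.
        if self.verdict not in ("prioritized", "benign", "unranked"):
            raise ValidationError(f"unknown verdict {self.verdict!r}")
        if not set(self.prioritized_genes) <= set(self.genes):
            raise ValidationError("prioritized_genes must be a subset of genes")
        if self.verdict == "benign" and not self.benign_match:
            raise ValidationError("verdict 'benign' requires a catalog match")
        if self.verdict == "prioritized" and not self.prioritized_genes:
            raise ValidationError("verdict 'prioritized' requires >= 1 prioritized gene")
        if self.verdict == "unranked" and self.prioritized_genes and not self.benign_match:
            raise ValidationError("gene-supported, catalog-free CNV cannot be 'unranked'")


def classify_verdict(has_prioritized_gene: bool, benign_match: bool) -> str:
    """The verdict rule: benign-catalog match vetoes prioritization."""
    if benign_match:
        return "benign"
    if has_prioritized_gene:
        return "prioritized"
    return "unranked"


@dataclass
class CohortSummary:
    n_patients: int
    n_cnv_prioritized_total: int
    per_patient_counts: dict[str, int]
    histogram: dict[int, int]
    yield_percent: float
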