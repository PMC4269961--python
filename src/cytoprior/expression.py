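"""Locus queries and the tissue-specific expression filter.

The first two prioritization filters: (1) map an imbalance/CNV interval to
the genes it contains; (2) keep the genes expressed more abundantly in the
affected tissue, detected as outliers of locus-aligned expression profiles.

A gene is selected for a target tissue when either

* its log2 target-tissue value exceeds the Tukey upper fence
  ``Q3 + fence_k * IQR`` computed over the locus genes' target-tissue values
  (high relative to its locus neighbours; needs >= 4 locus genes), or
* its robust cross-tissue z-score is >= ``z_min`` (high relative to the same
  gene's other tissues):

  ``z = (y_t - median_j y_j) / max(1.4826 * MAD_j y_j, 0.01)``

with ``y_j = log2(x_j + 1)`` across all tissues. The MAD floor of 0.01 keeps
flat profiles at z = 0 instead of +/-inf. With several target tissues a gene
passes if it passes in ANY of them.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .types import ExpressionMatrix, GeneAnnotation, GenomicInterval, SpecificityScore

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826  # makes MAD consistent with the SD under normality
MAD_FLOOR = 0.01


def genes_in_interval(
    annotation: Sequence[GeneAnnotation],
    interval: GenomicInterval,
    min_overlap_bp: int = 1,
) -> list[str]:
    """Genes whose intersection with ``interval`` spans >= ``min_overlap_bp``.

    Returned sorted by start coordinate, ties by symbol. An interval on a
    chromosome absent from the annotation yields an empty list with a logged
    warning (it is a data mismatch worth noticing, not an error).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    if not annotation:
        return []
    chroms = np.array([g.chrom for g in annotation])
    if interval.chrom not in chroms:
        logger.warning(
            "interval chromosome %r absent from annotation (%d records)",
            interval.chrom,
            len(annotation),
        )
        return []
    starts = np.array([g.start for g in annotation], dtype=np.int64)
    ends = np.array([g.end for g in annotation], dtype=np.int64)
    overlap = np.minimum(ends, interval.end) - np.maximum(starts, interval.start)
    hit = (chroms == interval.chrom) & (overlap >= min_overlap_bp)
    hits = [(annotation[i].start, annotation[i].symbol) for i in np.flatnonzero(hit)]
    hits.sort()
    return [symbol for _, symbol in hits]


def tissue_specificity_z(expr: ExpressionMatrix, gene: str, tissue: str) -> float:
    """Robust z-score of the gene's log2 expression in ``tissue`` relative to
    its profile across all tissues. Requires >= 2 tissues."""
    if expr.n_tissues < 2:
        raise ValidationError("tissue-specificity needs >= 2 tissues")
    y = np.log2(expr.row(gene) + 1.0)  # raises KeyError for unknown gene
    if tissue not in expr.tissues:
        raise KeyError(f"tissue {tissue!r} not in expression matrix")
    target = expr.log_value(gene, tissue)
    med = float(np.median(y))
    mad = float(np.median(np.abs(y - med)))
    scale = max(MAD_SCALE * mad, MAD_FLOOR)
    return (target - med) / scale


def tukey_upper_fence(values: np.ndarray, fence_k: float = 1.5) -> float:
    """Q3 + fence_k * IQR with linear-interpolation quartiles."""
    q1, q3 = np.percentile(np.asarray(values, dtype=float), [25.0, 75.0])
    return float(q3 + fence_k * (q3 - q1))


def select_locus_outliers(
    expr: ExpressionMatrix,
    locus_genes: Sequence[str],
    tissues: str | Sequence[str],
    z_min: float = 2.0,
    fence_k: float = 1.5,
) -> tuple[list[str], dict[str, SpecificityScore]]:
    """Select locus genes expressed more abundantly in the target tissue(s).

    Parameters
    ----------
    expr
        Expression matrix; locus genes missing from it are logged, skipped
        for selection, and reported as unscorable downstream.
    locus_genes
        Genes of the imbalance/CNV locus, e.g. from :func:`genes_in_interval`.
    tissues
        One target tissue or several; a gene passes if it passes in any.
    z_min, fence_k
        Thresholds of the dual outlier rule (see module docstring). The
        Tukey-fence arm needs >= 4 scorable locus genes; below that only the
        z arm applies (logged).

    Returns
    -------
    (selected, scores)
        ``selected`` sorted by descending target expression (max over the
        requested tissues), ties by symbol. ``scores`` maps every scorable
        locus gene to its best :class:`SpecificityScore` (the tissue with the
        highest z).
    """
    if isinstance(tissues, str):
        tissues = [tissues]
    if not tissues:
        raise ValueError("at least one target tissue is required")
    if expr.n_tissues < 2:
        raise ValidationError("tissue-specificity needs >= 2 tissues")
    for tissue in tissues:
        if tissue not in expr.tissues:
            raise KeyError(f"tissue {tissue!r} not in expression matrix")

    scorable = [g for g in locus_genes if g in expr]
    missing = [g for g in locus_genes if g not in expr]
    if missing:
        logger.info(
            "%d locus gene(s) absent from expression matrix (unscorable): %s",
            len(missing),
            ", ".join(sorted(missing)[:10]),
        )
    fence_ok = len(scorable) >= 4
    if not fence_ok and scorable:
        logger.info(
            "locus holds %d scorable gene(s) < 4; Tukey-fence rule skipped, "
            "z-score rule alone applies",
            len(scorable),
        )

    scores: dict[str, SpecificityScore] = {}
    selected: set[str] = set()
    for tissue in tissues:
        locus_y = np.array([expr.log_value(g, tissue) for g in scorable])
        fence = tukey_upper_fence(locus_y, fence_k) if fence_ok else math.inf
        for gene, y_t in zip(scorable, locus_y):
            z = tissue_specificity_z(expr, gene, tissue)
            outlier = bool(fence_ok and y_t > fence)
            if outlier or z >= z_min:
                selected.add(gene)
            best = scores.get(gene)
            if best is None or z > best.z:
                scores[gene] = SpecificityScore(
                    gene=gene,
                    tissue=tissue,
                    z=z,
                    locus_outlier=outlier,
                    target_expression=float(y_t),
                )
            elif outlier and not best.locus_outlier and math.isclose(z, best.z):
                best.locus_outlier = True

    def target_expr(g: str) -> float:
        return max(expr.log_value(g, t) for t in tissues)

    ordered = sorted(selected, key=lambda g: (-target_expr(g), g))
    return ordered, scores
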