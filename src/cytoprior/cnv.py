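"""CNV-level prioritization and cohort summarization.

A CNV is prioritized when it contains at least one prioritized gene and does
not look like a common population variant. The benign screen matches the call
against a DGV-like catalog by reciprocal overlap (default 0.5) at a minimum
population frequency (default 0.01); a match vetoes prioritization unless the
veto is disabled. Dosage (gain/loss) never changes the verdict — it is
carried through to reports only.

Cohort summary: per-patient prioritized-CNV counts (including the zero bin)
and the diagnostic yield, the percentage of patients carrying >= 1
prioritized CNV, rounded half-up to one decimal.
"""

from __future__ import annotations

from collections import Counter
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

from .errors import ValidationError
from .expression import genes_in_interval
from .types import (
    CNVCall,
    CohortSummary,
    GeneAnnotation,
    PrioritizedCNV,
    VariantCatalogEntry,
    classify_verdict,
)


def annotate_cnv(call: CNVCall, annotation: Sequence[GeneAnnotation]) -> list[str]:
    """Gene content of one CNV call (any overlap >= 1 bp counts)."""
    return genes_in_interval(annotation, call.interval, min_overlap_bp=1)


def benign_match(
    call: CNVCall,
    catalog: Sequence[VariantCatalogEntry],
    min_reciprocal_overlap: float = 0.5,
    min_frequency: float = 0.01,
) -> bool:
    """True iff some catalog entry on the same chromosome overlaps the call
    reciprocally by >= ``min_reciprocal_overlap`` (overlap / longer length)
    and has population frequency >= ``min_frequency``."""
    if not (0 < min_reciprocal_overlap <= 1):
        raise ValueError("min_reciprocal_overlap must be in (0, 1]")
    if not (0 < min_frequency <= 1):
        raise ValueError("min_frequency must be in (0, 1]")
    call_len = call.end - call.start
    for entry in catalog:
        if entry.chrom != call.chrom or entry.frequency < min_frequency:
            continue
        overlap = min(call.end, entry.end) - max(call.start, entry.start)
        if overlap <= 0:
            continue
        reciprocal = overlap / max(call_len, entry.end - entry.start)
        if reciprocal >= min_reciprocal_overlap:
            return True
    return False


def prioritize_cnvs(
    calls: Iterable[CNVCall],
    prioritized_genes: set[str],
    annotation: Sequence[GeneAnnotation],
    catalog: Sequence[VariantCatalogEntry] = (),
    min_reciprocal_overlap: float = 0.5,
    min_frequency: float = 0.01,
    benign_veto: bool = True,
) -> list[PrioritizedCNV]:
    """Apply the verdict rule to every call, in deterministic
    (patient, chrom, start) order. With ``benign_veto=False`` the catalog
    match is still reported but no longer blocks prioritization."""
    results: list[PrioritizedCNV] = []
    ordered = sorted(calls, key=lambda c: (c.patient_id, c.chrom, c.start, c.end, c.dosage))
    for call in ordered:
        genes = annotate_cnv(call, annotation)
        hits = [g for g in genes if g in prioritized_genes]
        matched = benign_match(call, catalog, min_reciprocal_overlap, min_frequency)
        veto = matched if benign_veto else False
        verdict = classify_verdict(bool(hits), veto)
        results.append(
            PrioritizedCNV(
                call=call,
                genes=genes,
                prioritized_genes=hits,
                benign_match=matched,
                verdict=verdict,
            )
        )
    return results


def round_half_up(value: float, decimals: int = 1) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def summarize_cohort(
    results: Sequence[PrioritizedCNV],
    patient_ids: Iterable[str],
) -> CohortSummary:
    """Cohort-level summary over the full roster.

    ``patient_ids`` is the complete roster; patients without any prioritized
    CNV contribute to the zero bin (and drag the yield down). A result whose
    patient is missing from the roster is an error.
    """
    roster = sorted(set(patient_ids))
    roster_set = set(roster)
    counts: Counter[str] = Counter()
    for res in results:
        pid = res.call.patient_id
        if pid not in roster_set:
            raise ValidationError(f"patient {pid!r} in results but not on roster")
        if res.verdict == "prioritized":
            counts[pid] += 1
    per_patient = {pid: counts.get(pid, 0) for pid in roster}
    histogram = dict(sorted(Counter(per_patient.values()).items()))
    n_patients = len(roster)
    n_positive = sum(1 for c in per_patient.values() if c >= 1)
    yield_percent = (
        round_half_up(100.0 * n_positive / n_patients) if n_patients else 0.0
    )
    return CohortSummary(
        n_patients=n_patients,
        n_cnv_prioritized_total=sum(per_patient.values()),
        per_patient_counts=per_patient,
        histogram=histogram,
        yield_percent=yield_percent,
    )
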