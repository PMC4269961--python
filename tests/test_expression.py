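"""Locus queries and the tissue-specific outlier filter."""

import math
import statistics

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from cytoprior.errors import ValidationError
from cytoprior.expression import (
    genes_in_interval,
    select_locus_outliers,
    tissue_specificity_z,
    tukey_upper_fence,
)
from cytoprior.types import ExpressionMatrix, GeneAnnotation, GenomicInterval


def matrix(rows: dict[str, list[float]], tissues: list[str]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=tissues))


def brute_force_genes_in_interval(annotation, interval, min_overlap_bp=1):
    """Independent O(n) oracle: plain per-record interval arithmetic."""
    hits = []
    for g in annotation:
        if g.chrom != interval.chrom:
            continue
        overlap = min(g.end, interval.end) - max(g.start, interval.start)
        if overlap >= min_overlap_bp:
            hits.append(g)
    hits.sort(key=lambda g: (g.start, g.symbol))
    return [g.symbol for g in hits]


class TestGenesInInterval:
    def test_empty_annotation(self):
        assert genes_in_interval([], GenomicInterval("chr1", 0, 10)) == []

    def test_half_open_boundary_excluded(self):
        ann = [GeneAnnotation("chr1", 100, 200, "A")]
        assert genes_in_interval(ann, GenomicInterval("chr1", 200, 300)) == []
        assert genes_in_interval(ann, GenomicInterval("chr1", 199, 300)) == ["A"]

    def test_absent_chromosome_warns_and_returns_empty(self, caplog):
        ann = [GeneAnnotation("chr1", 100, 200, "A")]
        with caplog.at_level("WARNING"):
            assert genes_in_interval(ann, GenomicInterval("chrX", 0, 10)) == []
        assert any("absent" in r.message for r in caplog.records)

    def test_min_overlap_threshold(self):
        ann = [GeneAnnotation("chr1", 100, 200, "A")]
        iv = GenomicInterval("chr1", 150, 300)
        assert genes_in_interval(ann, iv, min_overlap_bp=50) == ["A"]
        assert genes_in_interval(ann, iv, min_overlap_bp=51) == []

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(1, 60))
            ann = []
            for i in range(n):
                start = int(rng.integers(0, 10_000))
                ann.append(
                    GeneAnnotation(
                        f"chr{int(rng.integers(1, 4))}",
                        start,
                        start + int(rng.integers(1, 500)),
                        f"G{i}",
                    )
                )
            s = int(rng.integers(0, 10_000))
            iv = GenomicInterval(f"chr{int(rng.integers(1, 4))}", s, s + int(rng.integers(1, 2_000)))
            min_ov = int(rng.integers(1, 100))
            assert genes_in_interval(ann, iv, min_ov) == brute_force_genes_in_interval(
                ann, iv, min_ov
            )


class TestSpecificityZ:
    def test_flat_profile_gives_zero(self):
        m = matrix({"A": [5.0, 5.0, 5.0]}, ["t1", "t2", "t3"])
        assert tissue_specificity_z(m, "A", "t2") == 0.0

    def test_matches_independent_median_mad_computation(self):
        raw = [7.0, 7.0, 7.0, 63.0]
        m = matrix({"A": raw}, ["t1", "t2", "t3", "t4"])
        y = [math.log2(v + 1.0) for v in raw]
        med = statistics.median(y)
        mad = statistics.median(abs(v - med) for v in y)
        expected = (y[3] - med) / max(1.4826 * mad, 0.01)
        assert tissue_specificity_z(m, "A", "t4") == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(300.0)  # MAD floor engages: (6-3)/0.01

    def test_below_median_is_negative(self):
        m = matrix({"A": [10.0, 20.0, 30.0, 1.0]}, ["t1", "t2", "t3", "t4"])
        assert tissue_specificity_z(m, "A", "t4") < 0

    def test_lookup_and_precondition_errors(self):
        m = matrix({"A": [1.0, 2.0]}, ["t1", "t2"])
        with pytest.raises(KeyError):
            tissue_specificity_z(m, "B", "t1")
        with pytest.raises(KeyError):
            tissue_specificity_z(m, "A", "t9")
        single = matrix({"A": [1.0]}, ["t1"])
        with pytest.raises(ValidationError):
            tissue_specificity_z(single, "A", "t1")


def independent_fence(values, k=1.5):
    """Quartiles by hand with linear interpolation (no numpy)."""
    xs = sorted(values)
    n = len(xs)

    def quantile(q):
        pos = q * (n - 1)
        lo = int(math.floor(pos))
        hi = int(math.ceil(pos))
        return xs[lo] + (xs[hi] - xs[lo]) * (pos - lo)

    q1, q3 = quantile(0.25), quantile(0.75)
    return q3 + k * (q3 - q1)


class TestSelectLocusOutliers:
    tissues = ["brain", "t1", "t2", "t3", "t4"]

    def test_no_signal_selects_nothing(self):
        rows = {f"G{i}": [7.0] * 5 for i in range(10)}
        m = matrix(rows, self.tissues)
        selected, scores = select_locus_outliers(m, list(rows), "brain")
        assert selected == []
        assert len(scores) == 10

    def test_planted_tenfold_gene_is_the_only_selection(self):
        rng = np.random.default_rng(0)
        rows = {}
        for i in range(20):
            base = float(rng.uniform(50, 60))
            rows[f"G{i}"] = [base] * 5
        rows["G5"] = [rows["G5"][0] * 10.0] + rows["G5"][1:]
        m = matrix(rows, self.tissues)
        selected, scores = select_locus_outliers(m, list(rows), "brain")
        assert selected == ["G5"]
        fence = independent_fence([m.log_value(f"G{i}", "brain") for i in range(20)])
        assert scores["G5"].target_expression > fence
        assert scores["G5"].locus_outlier

    def test_fence_matches_independent_quantiles(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            values = rng.uniform(0, 10, size=int(rng.integers(4, 30)))
            assert tukey_upper_fence(values) == pytest.approx(
                independent_fence(values), abs=1e-9
            )

    def test_small_locus_skips_fence_rule(self, caplog):
        rows = {"A": [8.0, 1.0, 1.0, 1.0, 1.0], "B": [2.0] * 5, "C": [2.0] * 5}
        m = matrix(rows, self.tissues)
        with caplog.at_level("INFO"):
            selected, _ = select_locus_outliers(m, ["A", "B", "C"], "brain")
        assert selected == ["A"]  # z rule alone
        assert any("fence rule skipped" in r.message.lower() for r in caplog.records)

    def test_threshold_extremes(self, sim_small):
        locus = [g.symbol for g in sim_small.annotation[:20]]
        expr = sim_small.expression
        none_sel, _ = select_locus_outliers(
            expr, locus, "brain", z_min=math.inf, fence_k=math.inf
        )
        assert none_sel == []
        all_sel, _ = select_locus_outliers(
            expr, locus, "brain", z_min=-math.inf, fence_k=math.inf
        )
        assert sorted(all_sel) == sorted(locus)

    def test_missing_genes_skipped_not_silently(self, caplog):
        rows = {f"G{i}": [3.0] * 5 for i in range(5)}
        m = matrix(rows, self.tissues)
        with caplog.at_level("INFO"):
            selected, scores = select_locus_outliers(m, list(rows) + ["GHOST"], "brain")
        assert "GHOST" not in scores
        assert any("unscorable" in r.message for r in caplog.records)

    def test_any_tissue_rule(self):
        rows = {f"G{i}": [4.0] * 5 for i in range(6)}
        rows["G0"] = [4.0, 4.0, 4.0, 4.0, 400.0]
        m = matrix(rows, self.tissues)
        only_brain, _ = select_locus_outliers(m, list(rows), "brain")
        assert only_brain == []
        either, _ = select_locus_outliers(m, list(rows), ["brain", "t4"])
        assert either == ["G0"]


@given(
    seed=st.integers(0, 10_000),
    c=st.sampled_from([2.0, 10.0]),
)
def test_scale_invariance_of_selection(seed, c):
    """Multiplying all expression values by c > 0 changes no decision
    (values kept >= 1 so the log2 shift is uniform up to the MAD floor)."""
    rng = np.random.default_rng(seed)
    n_genes, n_tissues = 12, 6
    values = rng.uniform(1.0, 200.0, size=(n_genes, n_tissues))
    genes = [f"G{i}" for i in range(n_genes)]
    tissues = [f"t{j}" for j in range(n_tissues)]
    m1 = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=tissues))
    m2 = ExpressionMatrix(pd.DataFrame(values * c, index=genes, columns=tissues))
    s1, _ = select_locus_outliers(m1, genes, "t0")
    s2, _ = select_locus_outliers(m2, genes, "t0")
    assert s1 == s2


@given(seed=st.integers(0, 10_000), boost=st.floats(1.5, 100.0))
def test_monotonicity_raising_target_of_selected_gene(seed, boost):
    """Raising only the target-tissue value of a selected gene never
    de-selects it."""
    rng = np.random.default_rng(seed)
    n_genes, n_tissues = 10, 6
    values = rng.uniform(1.0, 100.0, size=(n_genes, n_tissues))
    values[3, 0] *= 50.0  # make one gene selected
    genes = [f"G{i}" for i in range(n_genes)]
    tissues = [f"t{j}" for j in range(n_tissues)]
    m1 = ExpressionMatrix(pd.DataFrame(values.copy(), index=genes, columns=tissues))
    s1, _ = select_locus_outliers(m1, genes, "t0")
    if "G3" not in s1:
        return
    values[3, 0] *= boost
    m2 = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=tissues))
    s2, _ = select_locus_outliers(m2, genes, "t0")
    assert "G3" in s2
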