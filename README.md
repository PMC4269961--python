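# cytoprior

Candidate-gene and CNV prioritization for molecular cytogenetics.

Array CGH and FISH find chromosome imbalances and copy-number variants
(CNVs), but a deletion or duplication typically spans tens of genes, and a
patient's call set mixes pathogenic events with benign population
polymorphisms. `cytoprior` is a small toolkit for clinical and research
cytogenetics that turns a segment-level finding into a ranked gene-level
hypothesis and a cohort-level summary:

1. **Locus query** — list the genes a segment `[start, end)` contains
   (BED-style 0-based half-open intervals).
2. **Expression filter** — keep genes *expressed more abundantly in the
   affected tissue*. On log2(x+1) values, a gene passes if its target-tissue
   value exceeds the Tukey upper fence `Q3 + 1.5·IQR` over the locus genes,
   **or** its robust cross-tissue z-score
   `z = (y_t − median_j y_j) / max(1.4826·MAD_j, 0.01)` is ≥ 2.
3. **Network ranking** — score survivors against phenotype seed genes:
   seed proximity `|N(g) ∩ S\{g}| / √deg(g)`, the fraction of the gene's
   pathways containing a seed, and a pathway-perturbation simulation
   (delete the gene, measure seed-connectivity loss `1 − L_after/L_before`,
   where `L` is the largest number of seeds sharing one connected component).
4. **Rank fusion** — per-evidence competition ranks combined as a weighted
   geometric mean of rank ratios, `fused = exp(Σ w_e ln(r_e/N) / Σ w_e)`;
   lower is better, and expression remains a hard filter.
5. **CNV verdicts and cohort yield** — a CNV is *prioritized* iff it holds
   ≥ 1 prioritized gene and does not match a benign-variant catalog
   (reciprocal overlap ≥ 0.5 at population frequency ≥ 0.01); the cohort
   summary reports the per-patient prioritized-CNV histogram and the
   diagnostic yield (% of patients with ≥ 1 prioritized CNV).

A fully seeded synthetic-data module generates all inputs (annotation,
expression matrix, scale-free interactome with a wired-in disease module,
pathway sets, patient cohort, benign catalog) with planted ground truth, so
the whole pipeline is testable and calibratable without external databases.

## Worked example

`examples/01_expression_filter.py` and `examples/02_network_ranking.py`
analyze a synthetic 45-gene terminal-7q deletion locus in which two genes
are elevated in the affected tissue and wired to the phenotype seeds:

```
locus chr7:152000000-158000000 holds 45 genes
genes passing the expression filter in 'spinal cord':
  MNX1: log2 target expression 12.19, robust z 531.0, locus outlier True
  LIMBR1: log2 target expression 11.70, robust z 530.5, locus outlier True

MNX1: fused score 0.0222 (lower is better), seed proximity 1.41, pathway overlap 1.00
LIMBR1: fused score 0.0264 (lower is better), seed proximity 1.41, pathway overlap 1.00
```

43 of 45 genes are filtered out (flat profiles score z = 0 and sit below
the locus fence); the two survivors are each adjacent to two of the four
seed genes (proximity 2/√2 ≈ 1.41), sit in a seed-containing pathway, and
end up with fused scores near the best attainable 1/45 ≈ 0.022.

`examples/03_cnv_cohort.py` runs a simulated 205-patient cohort end to end:

```
patients: 205, prioritized CNVs in total: 342
per-patient prioritized-CNV histogram (count: n_patients):
  0: 28
  1: 62
  2: 65
  3: 50
diagnostic yield: 86.3%
```

Most carriers harbor 1–3 prioritized CNVs; the yield is the percentage of
patients for whom the method proposes at least one candidate variant.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main results from scratch: it prioritizes the
worked 45-gene locus and then runs a 25-replicate planted-truth recovery
experiment on the default simulated cohort (printing gene precision/recall,
CNV balanced accuracy and mean diagnostic yield), writing the results file
to `--out`. All randomness derives from `--seed`.
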