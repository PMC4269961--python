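# Methods

This note documents the model behind `cytoprior`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate, and
the numerical conventions.

## The prioritization model

The toolkit implements a two-strategy prioritization: **filtering** (discard
candidates failing a criterion) followed by **ranking** (order survivors by
scored evidence), with a final **fusion** of evidence ranks. The candidate
universe for a case is the set of genes overlapping the chromosome imbalance
or CNV under study; an optional second pass extends the universe to genes
one network hop away from, or sharing a pathway with, an already-prioritized
gene ("genes outside the imbalance").

### Expression filter

All statistics are computed on `y = log2(x + 1)` because expression data is
multiplicative-noise data; the +1 keeps zeros finite. Two complementary
outlier notions are OR-ed:

- **Locus fence** (high relative to locus neighbours): a gene passes when
  its target-tissue `y` strictly exceeds the Tukey upper fence
  `Q3 + fence_k·IQR` over the locus genes' target-tissue values. Quartiles
  use linear interpolation. The fence needs ≥ 4 scorable locus genes;
  below that this arm is skipped with a logged notice.
- **Tissue specificity** (high relative to the same gene's other tissues):
  robust z-score `(y_t − median)/max(1.4826·MAD, 0.01)` across all tissues,
  passing at `z ≥ z_min`. The MAD floor of 0.01 log2 units makes a perfectly
  flat profile score exactly 0 rather than ±∞.

Defaults `fence_k = 1.5` and `z_min = 2.0` are the community-standard
outlier conventions for the two statistics. With several target tissues
(e.g. fetal brain plus cortex), a gene passes if it passes in **any** of
them — affected-tissue profiles are pooled, not intersected. Selection is
invariant to rescaling all expression values by a constant (the log2 shift
cancels in both arms, up to the MAD floor).

Genes absent from the expression matrix are *unscorable*: excluded from the
filter, flagged in the report, never silently dropped.

### Network and pathway evidence

Against a phenotype seed-gene set S (known disease/trait genes):

- **Seed proximity** `|N(g) ∩ S\{g}| / √deg(g)`: the simplest
  guilt-by-association statistic that damps hub genes. Diffusion/random-walk
  propagation is deliberately out of scope — evidence stays local and
  auditable.
- **Pathway overlap**: of the pathways containing g, the fraction that also
  contain another seed (0 for pathway-less genes).
- **Perturbation impact**: pathway alteration is simulated by deleting the
  candidate node(s) and measuring `1 − L_after/L_before`, where `L` is the
  number of seeds in the seed-richest connected component. Measuring on the
  seed subnetwork (not the global largest component) keeps the statistic
  about the phenotype's pathway. "Largest component containing a seed" is
  ambiguous when components tie; taking the maximum **seed count** over
  components resolves ties deterministically and preserves monotonicity
  under superset removal. A gene is never its own seed match in any of the
  three scores.

### Fusion and selection

Per evidence, candidates receive competition ranks (1 = best; ties share the
minimum rank; unscorable genes get worst rank N rather than exclusion, so
absence of evidence cannot drop an expression-passing gene). The fused score
is a weighted geometric mean of rank ratios (a rank-product statistic):
scale-free, order-based, invariant to duplicating an evidence with split
weights. Default weights are 1 for each of specificity z, proximity, pathway
overlap and perturbation impact.

Expression is a hard filter: no network score can rescue a gene that failed
it. In the full pipeline (`run_all`), the converse confirmation is also
demanded by default whenever interactome/pathway inputs are supplied: a
selected gene needs ≥ 1 strictly positive network/pathway evidence
(`require_network_evidence`). This mirrors the method's design — expression
selects, proteomic/metabolomic data confirm — and it is what makes the
planted-gene precision target reachable: the expression filter alone admits
~2–3 % of null genes by chance. The standalone `prioritize_genes` function
defaults to not requiring confirmation.

### CNV verdicts and cohort summary

A call is *benign* when a catalog entry on the same chromosome reaches
reciprocal overlap ≥ 0.5 (overlap / longer of the two lengths) at frequency
≥ 0.01 — community-conventional CNV-matching thresholds; both are
configurable. A benign match vetoes prioritization by default (the catalog
screens out natural genome variation); `benign_veto=False` reports both
signals without the veto. Otherwise a call is *prioritized* iff it holds
≥ 1 prioritized gene, else *unranked*. Gain vs loss never changes the
verdict. Diagnostic yield is rounded half-up to one decimal
(e.g. 181/205 → 88.3).

## The synthetic world

Defaults encode a stated scenario, chosen once:

| parameter | default | rationale |
|---|---|---|
| genes_per_chrom / n_chrom | 50 / 4 | a ~50-gene disease locus (the terminal-7q worked case spans 45 genes) plus background chromosomes |
| n_planted | 12 | the trisomy-21 worked case selects 12 locus outliers |
| n_tissues | 30 | a GTEx-scale tissue panel |
| effect_log2fc / noise_sd | 3.0 / 0.5 | planted affected-tissue effect ≈ 6 robust SDs — clearly detectable, as in the worked cases |
| baseline log2 mean | 5.0 | mid-range expression units |
| network_size / attachment_m | 200 / 2 | preferential-attachment interactome over all genes, mean degree ≈ 4 |
| n_seeds | 10 | a typical curated phenotype gene panel; each planted gene is wired to 2 seeds |
| n_patients / pathogenic_prob | 205 / 181÷205 | the clinical cohort scale; carrier probability calibrated to its 88.3 % yield |
| benign catalog | 50 entries, freq U[0.01, 0.2] | common CNVs; entries are kept ≥ 50 kb away from planted genes (common variation is depleted around dosage-sensitive disease genes), so truth classes cannot collide |

One global seed fans out to four independent substreams (genome, expression,
network, cohort); identical configs produce byte-identical files.

What the generator does **not** emulate: real chromosome lengths and gene
densities, correlated tissue profiles, probe-level noise, partial-penetrance
pathogenic CNVs, inherited-vs-de-novo structure, and seed-gene sets with
measurement error. A green recovery test therefore establishes that the
pipeline's rules compose correctly and detect the stated effect size — not
that the method resolves real clinical cases; the published worked cases
need external expression/interactome snapshots and are represented here only
by a shape-matched synthetic fixture (`cytoprior.demo`).

## Numerical conventions

- Coordinates: 0-based half-open everywhere; interval overlap is counted in
  bp and a ≥ 1 bp overlap assigns a gene to a CNV.
- Chromosome names are verbatim strings; inputs sharing no chromosome name
  abort the run (naming-convention mismatch) instead of silently reporting
  zero overlap.
- Ties: ranks use competition ranking; all output orderings break ties by
  gene symbol; CNV reports sort by (patient, chrom, start).
- Determinism: reports are payload-identical across reruns (sorted keys and
  records, no timestamps); expression TSVs round-trip floats bit-exactly
  (`repr` on write, round-trip parsing on read).
- Degenerate inputs: single-tissue matrices load but refuse specificity
  scoring; loci with < 4 scorable genes skip the fence arm; empty seed sets
  are rejected for proximity; a fully disconnected candidate simply scores 0
  everywhere and ranks last.

## Known limitations

- Gene identity is symbol-string equality; no alias resolution (the worked
  locus intentionally carries the non-standard spelling "LIMBR1" as printed
  in its source material).
- The manual literature re-evaluation step of the original workflow has no
  computable definition and is replaced by the transparent fused ranking.
- Evidence weights are not learned; pathways and edges are unweighted.
- The benign veto and the gene rule interact by a fixed policy (veto wins);
  cohorts where frequent variants overlap true disease genes will lose
  sensitivity unless the veto is disabled.
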