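# coelomyx

Analysis toolkit for studying the DNA-damage response of sea urchin
(*Strongylocentrotus purpuratus*) coelomocytes — the circulating immune cells
of the coelomic fluid — after genotoxic UVB challenge. The package covers the
desk-scale computational core of such a study end to end:

- **Synthetic data generation** (`coelomyx.simdata`): single-cell UMI count
  matrices produced as Poisson thinnings of correlated latent expression with
  cell-specific sequencing depths, four coelomocyte types (phagocytes,
  vibratile cells, red and colorless spherule cells) at realistic control
  proportions with planted marker genes, planted condition-DE genes and
  differential-co-expression pairs; bulk negative-binomial count tables in a
  2-condition × 5-timepoint × 3-replicate layout; image and dose–response
  fixtures for the functional assays. Everything is reproducible bit-for-bit
  from a seed, so every downstream stage is testable without deposited data.
- **Quality control** (`coelomyx.qc`): median ± 5·MAD total-count cell
  filtering, a ≥ 50-detected-cells gene filter, median-total normalization
  with log1p.
- **Cell typing** (`coelomyx.celltyping`): one-vs-rest rank-sum marker tests
  per cluster (BH-adjusted p < 0.05, log2FC > 0.5) and a marker dictionary
  mapping clusters to coelomocyte types (Pks1 → red spherule cells; SpTrf /
  TLR / SpC3 / Sp-B7L3 → phagocytes; dynein heavy chains → vibratile cells; a
  combined BPI + lysozyme + strongylocin signature with non-significant
  Pks1/phagocyte markers → colorless spherule cells), plus per-sample
  cell-type fractions and paired-t comparisons across conditions.
- **Differential expression** (`coelomyx.diffexpr`): pOverA (≥ 10 counts in
  ≥ 3 samples) filtering, median-of-ratios size factors, a per-gene NB Wald
  test with moderated method-of-moments dispersions, k = 2 k-means gene
  clustering with centroid-correlation top-gene selection (ρ > 0.85, top
  100), two-way treatment × time ANOVA of cluster means, and per-cell-type
  rank-sum condition DE with a strict |log2FC| > 1 volcano rule.
- **Depth-aware co-expression** (`coelomyx.coexpr`): the core statistical
  machinery — an iteratively reweighted least-squares moment estimator of
  latent gene–gene correlation under the Poisson measurement model, and a
  label-permutation test for treated-minus-control co-expression differences.
- **Shared statistics & enrichment** (`coelomyx.stats_enrich`):
  Benjamini–Hochberg, Wilcoxon rank-sum, paired t, one-way ANOVA + Tukey HSD,
  and GMT-driven hypergeometric over-representation.
- **Assay quantification** (`coelomyx.assays`): three-parameter logistic
  LD50 fitting, comet-assay tail-DNA percent, Otsu/triangle histogram
  thresholds, nuclei-normalized puncta density, and western-blot
  densitometry normalization.
- **Pipeline & CLI** (`coelomyx.pipeline`, `coelomyx` command): YAML-driven
  orchestration of all stages with one global seed and bit-identical reruns.

## The model at the core

UMI counts are treated as noisy readouts of latent relative expression. For
cell *i* with sequencing depth *s·i* and genes *j*, *k*:

    X_ij | z_ij ~ Poisson(s_i · z_ij),   E z_ij = μ_j,
    Cov(z_ij, z_ik) = σ_jk,   ρ_jk = σ_jk / √(σ_jj σ_kk)

Naive Pearson correlation of raw counts is attenuated by Poisson noise and
inflated by shared depth. The estimator removes both by solving the moment
conditions

    E[X_ij − s_i μ_j] = 0
    E[(X_ij − s_i μ_j)² − s_i μ_j − s_i² σ_jj] = 0
    E[(X_ij − s_i μ_j)(X_ik − s_i μ_k) − s_i² σ_jk] = 0

with iteratively reweighted least squares (weights = inverse estimated
variance of each condition), and tests σ_jk = 0 with the WLS slope over its
standard error against the standard normal. Differential co-expression
Δρ = ρ_treated − ρ_control is tested by pooling subsampled cells from the
two groups and permuting group labels (two-sided, add-one convention, BH
across pairs).

## Worked example

Recovering a planted latent correlation of 0.5 from sparse counts
(5,000 cells, mean ≈ 1 count/gene, log-normal depths):

```python
import numpy as np
from coelomyx import simdata, coexpr

rng = np.random.default_rng(0)
corr = np.eye(4); corr[0, 1] = corr[1, 0] = 0.5
s = simdata.draw_depths(rng, 5000, 5000.0, 0.5)
z = simdata._gamma_copula_draw(rng, 5000, np.full(4, 1 / 5000),
                               np.full(4, 0.45), corr)
X = rng.poisson(s[:, None] * z)
table = coexpr.estimate_coexpression(X, s, [(0, 1), (2, 3)])
print(table[["gene_j", "gene_k", "rho", "p", "q", "valid"]].round(4))
```

prints

```
 gene_j  gene_k     rho      p      q  valid
      0       1  0.5042 0.0000 0.0000   True
      2       3 -0.1209 0.1268 0.1268   True
```

The correlated pair is recovered at ρ̂ ≈ 0.50 (the naive count-level Pearson
for the same pair is 0.25 — attenuated to half the truth), while the
independent pair is not significant.

The full pipeline runs from a config:

```bash
coelomyx run --preset small --seed 3 --out results/
```

writing QC reports, cluster markers and type assignments, cell-type
fractions, single-cell and bulk DE tables, co-expression and differential
co-expression records, enrichment results and a manifest with per-stage
seeds and output hashes. Running the same command twice produces
byte-identical outputs.

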