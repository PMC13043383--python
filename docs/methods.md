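# Methods

This note documents the models, estimators and numerical choices behind
`coelomyx`, what the synthetic-data generator does and does not emulate, and
the design decisions made where the design was genuinely open.

## Measurement model and synthetic single-cell data

Counts are modelled as Poisson thinnings of latent expression:
`X_ij | z_ij ~ Poisson(s_i z_ij)` with `E z_ij = mu_j` and
`Cov(z_ij, z_ik) = sigma_jk`. The generator draws latent vectors with gamma
marginals coupled through a Gaussian copula: gamma keeps `z > 0` and gives
counts a negative-binomial-like overdispersion after Poisson mixing, while
the copula provides direct control of the dependence. The copula correlation
is treated as the "true" ρ in recovery experiments.

**Copula vs product-moment gap.** The estimator recovers the product-moment
correlation of the latent draws, which for skewed gamma marginals is
slightly smaller in magnitude than the copula parameter (the gap grows with
the marginal CV and is larger on the negative side, where skewed marginals
cannot reach −1). The generator's default latent CV is **0.45**, where the
gap is ≈ 0.01 at ρ = +0.5 and ≈ 0.03 at ρ = −0.5 — inside the ±0.05 recovery
tolerance that budget absorbs. At CV = 1 (exponential marginals) the gap at
ρ = −0.5 would be ≈ 0.14, which is why the CV is a deliberate default, not a
free dial.

**Defaults.** Cell-type proportions follow control coelomic fluid
(phagocytes 0.79, vibratile 0.07, red spherule 0.06, colorless spherule
0.08); three samples per condition; marker genes elevated 8-fold in their
type; condition-DE genes shifted by log2FC = 2 in the treated condition;
differential-co-expression pairs switch their copula ρ between conditions
inside phagocytes only (the cell type the co-expression analysis targets).
Depths are log-normal with CV 0.5, rescaled to a mean of 5,000 — a realistic
UMI depth spread. Relative gene means are log-normal, normalized to sum
to 1. All randomness flows from a single `numpy` Generator per design seed;
regeneration is bit-identical.

**Not emulated:** ambient RNA, doublets, batch effects, read-level data.
Cluster labels in the generator equal the true cell type, so typing tests
measure marker-rule correctness, not clustering quality. Passing tests
therefore demonstrate correctness of the estimators under the stated
measurement model, not robustness to the artifacts real preprocessing
removes.

**PSD repair.** Requested correlation matrices are repaired once by
eigenvalue clipping at zero with the unit diagonal restored; a matrix still
indefinite afterwards raises an error naming the worst off-diagonal pairs.

## Quality control

Cells are removed when total counts fall beyond `n_mads` (default 5) median
absolute deviations of the median total. "Absolute deviations" is read as
the unscaled MAD on raw totals (no 1.4826 consistency factor, no prior log
transform), removal is two-sided, and the bounds are inclusive. A zero MAD
with non-identical totals falls back to the mean absolute deviation with a
warning; identical totals remove nothing. Genes detected in fewer than 50
cells are dropped. Normalization scales each cell to the median
pre-normalization total (the target sum was an open choice; the median is
scanpy's default and keeps values on a count-like scale) followed by
natural-log log1p; raw counts are retained in a layer.

## Cell typing

Markers are ranked one-vs-rest per cluster with a Wilcoxon rank-sum test on
log-normalized values; the log2 fold change is the ratio of group means on
the normalized (pre-log) scale with pseudocount 1; BH adjustment is within
cluster; a marker is significant at adjusted p < 0.05 and log2FC > 0.5
(log2 — consistent with the bulk thresholds' explicit log2 scale).
Dictionary rules are evaluated in fixed precedence red spherule → phagocyte
→ vibratile → colorless spherule: Pks1 is the only definitive single-gene
marker, and colorless spherule cells are partly defined by exclusion
(non-significant Pks1 and phagocyte markers), so they are evaluated last.
Gene groups are fnmatch patterns so families (SpTrf*, Tlr*, Dyhc*) resolve
against whatever identifiers the matrix uses; unresolvable groups are an
error. Cell-type fractions are per-sample counts over sample totals
(unassigned included); condition comparisons use a two-sided paired t-test
with a degenerate-variance flag when all paired differences vanish.

## Bulk differential expression

The pOverA filter retains genes with ≥ 10 counts in ≥ 3 samples after
dropping all-zero rows. Size factors are DESeq2-style median-of-ratios over
a geometric-mean pseudo-reference restricted to genes nonzero in every
sample. The per-timepoint test is a Wald test of the log difference of
normalized group means (pseudocount 0.5) with a delta-method standard error
under `Var(y) = mu + alpha mu^2` for normalized counts. Treating normalized
counts on the common scale (rather than re-introducing per-sample factors in
the variance) keeps the test an exact function of the normalized data, so
multiplying a sample's counts and its size factor jointly changes nothing.

**Dispersion moderation.** The per-gene dispersion is a pooled
method-of-moments estimate from the within-group variances. At triplicate
sample sizes this estimate has 4 degrees of freedom, and referring the Wald
statistic to a standard normal with so noisy a denominator is badly
anticonservative (the statistic behaves like t₄ when overdispersion
dominates), while a t₄ reference destroys power. No per-gene fix escapes
this trade-off — it is the reason limma/edgeR/DESeq2 share dispersion
information across genes. The package therefore moderates each gene's MoM
dispersion toward the dataset median with 20 prior degrees of freedom
(trend-free empirical Bayes; DESeq2's parametric mean-dispersion trend and
shrinkage remain out of scope) and refers the Wald statistic to a t
distribution with residual + prior df. Under the generator's conditions this
yields null type-I ≈ 0.05–0.06, empirical FDR ≈ 0.01 at BH 0.05 and
sensitivity ≈ 1.0 for log2FC = 2 effects.

The variance-stabilizing transform for clustering is `log2(normalized + 1)`
— the downstream uses (k-means, centroid correlations, heatmaps) are robust
to the precise transform. k-means runs with k = 2, 25 restarts, Lloyd
iterations to tolerance 1e-6 at a fixed seed on row-mean-centered profiles;
clusters are ordered so cluster 1 has the larger treated-minus-control mean
("up-regulated" first); per gene the Pearson correlation with the cluster
centroid selects up to 100 genes at ρ > 0.85. Cluster means feed a
treatment × time ANOVA with Type-II sums of squares (order-invariant under
the mild imbalance of a lost replicate). Single-cell condition DE is a
rank-sum test within cell type with BH across genes and strict volcano
thresholds (q < 0.05 and |log2FC| > 1); this replaces a variational
Bayesian DE, a recorded fidelity gap — rank-sum p-values and posterior
fold-change summaries need not coincide gene by gene.

## Depth-aware co-expression

Marginal parameters (mu_j, sigma_jj) solve the first two moment conditions
by IRLS: unit weights initialize; each iteration recomputes
`g_ij = s_i mu_j + s_i^2 sigma_jj` (the model variance of `X_ij`, clipped
below at 1e-10) and reweights the mean equation by `1/g` and the variance
equation by `1/g^2`; iteration stops at relative tolerance 1e-5 or 10
iterations, returning the last iterate with per-gene convergence flags.
Covariances then solve the third condition in closed form with weights
`1/(g_ij g_ik)`; the z statistic is the WLS slope times the square root of
the weighted design sum (the slope's inverse standard error under the null),
referred to the standard normal. ρ̂ is clipped to [−1, 1]; negative latent
variances are clipped to zero and the pair flagged invalid (ρ undefined), a
self-pair reports ρ = 1 whenever its variance is positive. Depths are the
per-cell total UMI count over all genes of the matrix when not supplied
explicitly. Retention of significant pairs uses strict q < 0.05 and signed
ρ̂ > 0.5 (the signed reading of the "> 0.5" filter; an absolute-value variant
is a one-line change on the record table).

The permutation test subsamples `min(n_per_group, available)` cells per
group once (seeded, without replacement), computes Δ̂ = ρ̂_trt − ρ̂_ctrl,
pools the subsamples, and permutes group labels B times, re-estimating all
marginals and covariances each round (defaults n_per_group = 10,000,
B = 1,000). The two-sided p uses the add-one convention
`(1 + #{|Δ_b| ≥ |Δ̂|})/(B + 1)`, so p = 1/(B+1) is the floor and zero
p-values cannot occur; permutation rounds with an invalid estimate for a
pair are dropped for that pair, reducing its B (recorded per pair). Labels
are permuted over a fixed subsample rather than re-subsampled each round —
the literal reading of the described procedure and substantially cheaper.

## Assays

- **LD50:** `V(d) = V_max / (1 + (d/LD50)^h)` with a floor of 0 — the
  adopted reading of a "three-parameter mode" logistic (the proprietary
  parameterization is unpublished). Least squares over a multi-start grid
  (log-spaced LD50 initials × h ∈ {0.5, 1, 2, 4}); LD50 is reported in input
  dose units; a never-decreasing dose–viability table returns a no-kill
  sentinel (LD50 = +inf).
- **Comet:** tail DNA % = 100 · tail/(head + tail) integrated intensity over
  disjoint input masks (segmentation itself is out of scope; masks come from
  fixtures or external tools); per-slide means require ≥ 50 scored cells.
- **Thresholds:** Otsu maximizes between-class variance over the histogram
  (lowest level on ties); triangle takes the level of maximum perpendicular
  distance from the peak-to-far-end chord on the longer flank. 8-bit images
  use exact 256-level histograms; other dtypes are binned to 256 levels.
- **Autophagy signal:** the FITC channel is triangle-thresholded and pixel
  intensities integrated over the foreground; nuclei are counted by Otsu +
  connected components with distance-transform peak splitting of merged
  blobs (a deliberate simplification of watershed; each component counts
  max(1, peaks)). The output is integrated density per nucleus. Integrating
  over the foreground before dividing (rather than area-averaging first)
  differs from the alternative reading by a per-image constant; the
  area-averaged variant can be formed from the returned integrated density
  and foreground mask.
- **Densitometry:** normalized = (lane − background)/(control −
  control background); a control at or below its background is an invalid
  blot. Downstream inference is the one-tailed paired t-test.

## Problem sizes and runtime

The test suite and acceptance script run simulations at the scales the
statistical claims are stated for: 50 × 5,000-cell datasets for estimator
recovery; 100 exchangeable-null pairs at 2,000 cells/group with B = 200 for
calibration and 20 planted pairs at 5,000 cells/group for power; 2,000-gene
bulk simulations at n = 3 + 3; twenty ~2,000-cell cohorts for typing. The
whole suite completes in a few minutes on a single CPU.

## Known limitations

- The generator's clusters are the true types; marker-rule evaluation is
  decoupled from clustering error.
- The NB Wald test's moderation assumes dispersions are exchangeable across
  genes (no mean-dispersion trend); strongly trending dispersion would make
  the moderation target a compromise.
- The permutation test's fixed-subsample design conditions on one subsample;
  its p-values are exact for the subsample, slightly conservative about the
  full-population difference.
- The copula correlation is a dependence parameter, not exactly the latent
  Pearson correlation; recovery statements are therefore made with the
  ±0.05 tolerance noted above.
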