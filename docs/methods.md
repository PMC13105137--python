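# Methods

## Overview

`netprs` constructs polygenic risk scores (PRS) for a quantitative
target trait from GWAS summary statistics alone, borrowing strength
from genetically correlated traits through a network annotation. The
pipeline has five stages:

1. **Trait selection.** Cross-trait LD score regression estimates the
   genetic covariance between the target and each candidate trait;
   candidates passing a Bonferroni threshold (p < α/K) are retained as
   relevant traits.
2. **Network annotation.** A signed bipartite genotype–phenotype
   network (GPN) links the M SNPs to the K relevant traits with edge
   weights T_mk = sign(β̂_mk) · Q_χ²₁(1 − p_mk). Per-SNP degree
   (d_m = Σ_k |T_mk|) and approximate betweenness (unit mass per
   connected trait pair, split evenly over the SNPs adjacent to both)
   summarize pleiotropic relevance, and are max-normalized to
   s_m ∈ (0, 1].
3. **Penalized regression.** Standardized marginal effects
   β̃_m = z_m/√n_m and a blockwise reference-panel LD matrix R define
   the objective f(β) = ½β'Rβ − β̃'β + Σ_m τ_m|β_m| with
   τ_m = λ0 + λ1/s_m, minimized by cyclic coordinate descent with
   soft-thresholding. High-annotation SNPs receive smaller penalties.
4. **Tuning and evaluation.** When individual-level data exist, samples
   split 60/20/20 into train/validation/test. Otherwise the sufficient
   statistic X'y is partitioned by conditional-normal subsampling and
   R² is approximated from summary statistics.
5. **Scoring.** PRS = X'β̂ with dosages standardized by reference
   allele frequencies.

## Model assumptions

The solver assumes genotypes and phenotype are standardized to zero
mean and unit variance, so per-allele effect sizes never enter the
optimization: everything runs on β̃ = z/√n, making the fit invariant to
allele-frequency scaling and to simultaneous allele flips. LD is
assumed block-banded (cross-block correlation exactly zero), matched to
the banded estimation from the reference panel. The annotation is
assumed exchangeable with the training GWAS — i.e. the relevant traits'
summary statistics are treated as external data, so no correction is
made for the target trait's possible overlap with them (the LDSC
intercept absorbs overlap only at the trait-selection stage).

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| LD window | 250 SNPs | block width for banded LD; blocks decouple the solver and bound memory |
| LD shrinkage | 0.1 | off-diagonal shrinkage toward 0; with eigenvalue clipping guarantees PSD blocks, hence a convex objective and monotone descent |
| edge_alpha | 0.05 | p-value cut for the binarized GPN topology used by betweenness |
| annotation floor ε | 0.01 | lower bound on s_m so τ_m = λ0 + λ1/s_m stays finite; a SNP at the floor is effectively excluded once λ1 is active |
| tol | 1e-4 | convergence: max absolute coordinate change per sweep, on the standardized scale |
| max_iter | 1000 | sweep cap |
| jackknife blocks | 200 | contiguous delete-one blocks for LDSC standard errors (reduced proportionally when M is small) |
| fractions | 0.6/0.2/0.2 | train/validation/test split in both evaluation modes |

λ grids in the experiment helpers are expressed as fractions of
max|β̃| ({0.5, 0.3, 0.15, 0.08, 0.04, 0.02} for λ0 and
{0, 0.01, 0.05, 0.15} for λ1), so the path spans from the empty model
to a nearly unpenalized one regardless of signal strength. Because
λ1 = 0 is always in the grid, the plain lasso is nested inside the
NetPRS model space.

## Numerical choices

- **Penalty form.** The annotation enters as λ1/s_m (not λ1·s_m): a
  larger annotation must mean a smaller penalty. The alternative
  reading is available via `penalty_form="times"` for sensitivity
  analysis.
- **Degree aggregation.** Degree sums |T_mk|; a signed sum would let
  opposite-direction associations cancel and break the interpretation
  of degree as pleiotropic strength. A signed mode exists behind a
  flag.
- **PSD enforcement.** Sample-correlation blocks are shrunk
  off-diagonally, eigenvalue-clipped at 0, and rescaled to unit
  diagonal. This keeps the coordinate-descent objective convex; the
  clip resolves any non-uniqueness from rank-deficient panels.
- **p-value clamping.** p-values are clamped to [1e-300, 1] before
  chi-square quantile inversion; entries at the clamp use z² directly.
- **Sweep order.** Cyclic in genomic position. The objective is convex,
  so the optimum is unique for positive-definite blocks; order affects
  only the path, not the limit (verified against a generic convex
  solver).
- **Warm starts.** Grid tuning traverses λ0 in decreasing order within
  each λ1, warm-starting from the previous solution; the first cell is
  cold-started at β = 0.
- **Subsampling moments.** The training partition of X'y is drawn from
  N((n/N)·X'y, n(N−n)/N·Σ). The mean fraction n/N is forced by
  E[X_tr'y_tr] under random subsampling of n of N individuals; the
  variance is the finite-population (hypergeometric-style) form. A
  literal mode with mean fraction (N−n)/N is selectable
  (`mean_mode="literal"`) but is not the default because it contradicts
  the expectation identity (a 60% training split would shrink the
  statistic to 40%).
- **Σ proxy.** The per-observation covariance of x_j·y is proxied by
  the blockwise LD matrix with unit diagonal (exact under a null-ish
  polygenic signal on the standardized scale); `ld=None` gives the
  deterministic zero-noise split.
- **Per-SNP sample sizes.** β̃ uses per-SNP n; wherever a scalar N is
  required (partitioning, R² approximation) the median n is used.
- **Degenerate annotations.** If every raw centrality is zero the
  normalized annotation is set to all ones, reducing NetPRS exactly to
  the uniform lasso rather than producing an undefined penalty.

## The simulator

`trait_simulator` draws K correlated quantitative traits under the
matrix-normal model Y = XB + E:

- **Genotypes**: Gaussian-copula Hardy–Weinberg dosages. Latent
  per-block AR(1)(ρ = 0.5, block 25 SNPs by default) Gaussians are
  thresholded at the HWE class quantiles of per-SNP MAFs drawn
  uniformly from (0.05, 0.5). This gives seedable, dependency-free
  genotypes with controllable LD — not coalescent realism: no allele
  frequency spectrum, no recombination hotspots, no long-range LD, no
  population structure.
- **Effects**: ⌈p·M⌉ causal SNPs drawn uniformly; causal rows are
  i.i.d. N(0, Σ_g/(p·M)) with Σ_g[k,s] = rg_ks·√(h²_k h²_s), so the
  per-trait genetic variance is h²_k and causal effects are correlated
  rg across traits. Heritability is defined at the standardized-genotype
  scale; realized Var(XB) ≈ h² without rescaling.
- **Noise**: rows jointly N(0, Σ_e) across traits for overlapping
  individuals, Σ_e[k,s] = re_ks·√((1−h²_k)(1−h²_s)) with diagonal
  1−h²_k; independent for disjoint individuals (cross-cohort noise
  correlation between different people is not meaningful). `re` is
  accepted as a correlation, symmetric with the `rg` convention.
- **Overlap**: `complete` shares one genotype matrix; `partial` shares
  the first N_s rows; `none` draws all cohorts independently — always
  from the same MAF/LD population.
- **GWAS**: vectorized per-SNP simple linear regression (slope,
  residual SE on n−2 df, two-sided t p-value).

Because the generator's LD is block-exact and its architecture is
Gaussian, passing tests demonstrate correctness of the estimators and
solver under the stated model — not robustness to real-data features
like mismatched reference ancestry, imputation error, or non-normal
effect-size distributions.

## Benchmark scales

The repository's standing experiments use desk scales chosen once as
the package's study design:

- **Concordance grid** (`concordance_experiment`): 8 settings
  (K ∈ {5,10} × h² ∈ {0.2,0.6} × rg ∈ {0.1,0.6}), N = 2000, M = 1000,
  p = 0.01, re = 0.1, partial overlap with 40% shared individuals
  (the proportion corresponding to 2000 of 5000), 5 repeats per
  setting.
- **Head-to-head** (`head_to_head`): K = 5, N = 2000, M = 500,
  h² = 0.6, rg = 0.6, 10 seeds, NetPRS vs the nested plain lasso and a
  uniform-annotation arm.
- **LDSC recovery**: pairs with h² = 0.6, rg ∈ {0, 0.6}, M = 2000,
  n = 5000, infinitesimal architecture (p = 1, the model LDSC assumes),
  reference panel of 500 individuals with small-sample-adjusted LD
  scores. The genetic correlation is formed as ρ̂_g/√(ĥ²₁ĥ²₂) with a
  joint block jackknife, which cancels the attenuation that noisy
  reference LD scores induce in each slope separately.

## Known limitations

- Banded LD ignores real long-range LD (e.g. MHC); the residual
  correlation sum in the coordinate update runs within blocks only.
- The R² approximation omits the LD term in Var(PRS) and proxies
  Var(y) by N·max_m(SE²_m σ²_m); it is a ranking device for tuning and
  mode-concordance, not an unbiased R² estimator.
- No binary-trait (liability-scale) support; no covariates; no
  multi-ancestry LD; no VCF ingestion.
- The LDSC implementation is the minimal estimator (unweighted, free
  intercept, block jackknife) — not a replacement for the full ldsc
  tool.
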