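# Methods

## Problem and model

`namdd` maps DNA methylation sites to a binary disease status *through*
gene expression. The data are three sample-aligned blocks: methylation
X ∈ R^{N×P}, expression Y ∈ R^{N×Q}, and status z ∈ {0,1}^N. Two edge
layers are estimated:

**Methylation → gene.** A multivariate sparse-group regression

    min_B  ½‖XB − Y‖²_F + α‖B‖₁ + β Σᵢ ‖bⁱ‖₂

whose elementwise L1 term sparsifies individual site–gene coefficients and
whose row-group term removes whole sites at once (only a few sites should
influence any gene). It is solved by ADMM after splitting B into a proxy W
with dual Λ:

    W ← prox of the penalties at B + Λ
    B ← (XᵀX + ρI)⁻¹ (XᵀY + ρ(W − Λ))
    Λ ← Λ − (W − B)

The penalty prox is applied through generalized *p*-shrinkage maps with
exponents u, v ≤ 1,

    S_u(b, α)ᵢ = sign(bᵢ) · max{0, |bᵢ| − α^{2−u}|bᵢ|^{u−1}},

elementwise at (α, u) and then row-wise on the L2 norms at (β, v). At
u = 1 this is the classical soft threshold (so u = v = 1 recovers the
convex sparse-group lasso, which the test suite verifies against an
independent coordinate-descent LASSO); at u < 1 the map keeps the same
kill region |b| ≤ α but shrinks surviving coefficients by less, reducing
the bias on large effects. Zero inputs map to zero by convention (the
max{0, ·} guard makes the |b|^{u−1} singularity unreachable).

**Gene → disease.** L1-regularized logistic regression
min_θ Σᵢ −log p(zᵢ|yᵢ; θ) + λ‖θ‖₁, fit by proximal gradient descent
(ISTA) with a monotone backtracking line search and a Lipschitz step
initialized from ‖[Y, 1]‖²/4. An unpenalized intercept is included by
default: half-samples drawn during stability selection can be mildly
class-imbalanced, and an intercept-free fit would convert that imbalance
into selection bias. It can be disabled (`fit_intercept=False`).

## Stability selection and edge scores

Both layers are refit on T random half-samples (⌊N/2⌋ samples, drawn
class-stratified so the logistic layer always sees both classes). The
score of an edge is the fraction of refits in which its coefficient is
nonzero (|coef| > 1e-8); edges with score ≥ ϕ ∈ (0.5, 1] are selected.
Under the usual exchangeability assumptions the expected number of false
selections per gene is bounded by c²/((2ϕ−1)P), with c the number of
nonzero coefficients the solver reports at the chosen penalties; c is
counted per response column, since the bound is applied per gene. The
test suite checks this bound empirically on pure-noise data.

Penalties (α, β, λ) are cross-validated once on the full data — held-out
residual error for the regression layer, held-out deviance for the
logistic layer — and held fixed across the T refits. Re-running CV inside
every half-sample would multiply cost roughly tenfold for no change in
the score's interpretation.

## Paths and significance

Selected edges form a tripartite network (sites → genes → one disease
node). A path is a length-2 chain site → gene → disease; its score is the
sum of its two edge scores, hence lies in [2ϕ, 2] with the ceiling 2
attained when both edges are selected in every resample. In this
tripartite setting exhaustive enumeration of (site, gene) pairs is exact,
so the K best paths are found by enumeration and sorting (ties broken by
(gene, site) lexicographic order for reproducible cutoffs).

Path significance uses a permutation null: rows of X, rows of Y and
entries of z are permuted with three independent seeded streams,
destroying all cross-block coupling while preserving every column's
marginal distribution. The path's score is recomputed on each permuted
dataset through the stability pipeline at a reduced resample count
(default T = 20; only the score's rank against the null matters, so
resolution 1/T suffices) with penalties held at their observed-data
values. The default P-value is the fraction of null scores strictly
smaller than the observed score ("literal" mode: 8 of 1000 below gives
p = 0.008). Note this direction is inverted relative to the conventional
upper tail, which is available as `mode="upper"`; both are exposed and
the ambiguity is documented rather than resolved silently. Strict
inequality is used; ties are reported separately.

## Screening

For array-scale P the solver is preceded by a univariate filter: each
site's least-squares slope against every gene (columns mean-centered, so
no intercept), keeping the d sites with the largest |slope| per gene
(union over genes; ties to the smaller site index). d defaults to 200 —
targeted analyses typically retain a few hundred sites and no principled
default exists; the value is explicitly arbitrary and
irrelevant for P ≤ a few thousand, where screening is skipped.

## Synthetic benchmark generator

The generator emulates a genuine two-hop causal mechanism:

1. Balanced labels: ⌊N/2⌋ controls, ⌈N/2⌉ cases, shuffled.
2. Causal methylation: entry (i, j) ~ Normal(class_shift · zᵢ · sⱼ, 1)
   with a random per-site sign sⱼ ∈ {−1, +1}, so hyper- and
   hypo-methylated disease sites are equally likely. class_shift
   defaults to 1.0 (one within-class SD of separation per site — weak
   individually, strong jointly across 150 sites).
3. A fully connected 150→10→1 sigmoid network (cross-entropy loss,
   full-batch gradient descent, learning rate 0.5) is trained on the
   causal sites until label accuracy exceeds 95% (up to 5
   re-initializations); its hidden activations become the 10 causal gene
   columns, which therefore genuinely mediate between methylation and
   disease.
4. 850 null sites ~ N(0,1) and 90 null genes ~ Normal with the causal
   genes' pooled mean and variance are appended; N(0,1) noise is added
   to the null block (adding it to the causal block as well is exposed
   as `noise_target="all"`); columns are shuffled and the causal indices
   recorded.

What this emulates: per-site effects that are individually weak (a dense
mixture of 150 sites bounds any single site–gene correlation near
1/√150), detectable only jointly and increasingly with N — the regime
the method is designed for. What it does not emulate: beta-value
distributions bounded in [0,1], CpG correlation blocks, batch effects,
or gene–gene regulatory structure. Passing the recovery benchmarks
therefore demonstrates the pipeline's statistical machinery, not
robustness to array artefacts.

Because training stops at the accuracy criterion, the hidden weights stay
close to their random initialization; causal sites enter genes with
small, undirected weights. Causal sites are also mutually correlated
through the label (≈ class_shift²/4 pairwise), which deflates their
ridge-path coefficients relative to independent null sites. Both effects
make N = 200 genuinely hard (AUC near chance) and recovery at N = 800
the meaningful target, matching the method's qualitative claim that it
needs and rewards larger cohorts.

## Numerical choices

- **Standardization.** Columns of X and Y are standardized inside each
  solve (and per half-sample) so one penalty scale applies to all
  features; coefficients are reported on the standardized scale. The
  logistic stability layer standardizes Y likewise.
- **Splitting weight ρ.** The ADMM fixed point does not depend on ρ, but
  the dual (which must climb to the residual-correlation scale ≈ √N
  before an inactive coefficient can activate) climbs ρ times faster for
  larger ρ. The solver's own default is ρ = 1; pipeline runs use ρ = 20
  (`AnalysisConfig.rho`), which reaches a stable support an order of
  magnitude sooner. The dual step is the scaled form Λ ← Λ − (W − B);
  stepping by ρ(W − B) diverges for ρ > 1.
- **Penalty grids.** With an unnormalized ½‖XB−Y‖² loss on standardized
  data the relevant penalty scale is the noise inner-product scale
  √N_half. Defaults alpha_grid = [20, 35], beta_grid = [10, 17],
  lambda_grid = [0.5, 2, 8] bracket that scale for cohorts of a few
  hundred samples; held-out error genuinely discriminates here (denser
  fits overfit, emptier fits underfit), so CV is informative. On data at
  a very different scale, supply grids in the config.
- **Convergence.** Primal residual max|W − B| ≤ tol (default 1e-6;
  pipeline runs use 1e-4) or max_iter (default 500). With u < 1 the prox
  map is continuous but not contractive, and borderline coefficients can
  limit-cycle; the iteration cap is then the effective stopping rule. A
  residual growing for 50 consecutive iterations raises a convergence
  error; such half-samples are dropped from the stability denominator
  (hard error if more than 10% fail).
- **Ties and determinism.** Screening ties break to the smaller site
  index; path ties to (gene, site) lexicographic order; one master seed
  spawns per-subsample seeds, so every pipeline stage is reproducible
  bit-for-bit from the config.

## Benchmark harness

Per-site evidence for ROC purposes is the best path evidence touching
the site: max over disease-connected genes (gd score ≥ ϕ) of the
site's mg score, zero if no partner gene survives. Sweeping this score
traces a full ROC per run (reported AUC uses midrank tie handling);
thresholding it at ϕ gives the called-site set used for accuracy and for
the sample-exchange test, where a run on the true labels is contrasted
with a run on labels partially swapped between classes. Benchmark
defaults are desk-scale (T = 20, 5 repetitions, 3 CV folds over the
default grids, solver capped at 150 iterations with ρ = 20); the
full-scale protocol (T = 100, 20 repetitions, sample sizes 200–1100) is
the same code with larger settings.

## Known limitations

- The nonconvex regime (u, v < 1) has no global-optimality guarantee;
  the solver is validated exactly only in its convex limit.
- The false-positive bound assumes exchangeability the data may violate;
  it is checked empirically only on iid noise.
- The default permutation P-value direction (fraction of null scores
  below the observed) is counter-conventional; see above.
- The generator's causal law (class-conditional Gaussian with per-site
  signs) is one of many consistent with a two-hop mechanism; conclusions
  about real 450k data require real data.
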