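# Methods notes

This note records the statistical models the package implements, the
numerical choices behind them, what the synthetic generator does and does
not emulate, and the design decisions taken where more than one convention
exists.

## Trees and phylogenetic covariance

A rooted phylogeny with branch lengths implies, under Brownian motion, the
trait covariance `C[i,j] = depth of MRCA(i,j)` with `C[i,i]` the root-to-tip
length.  Pagel's λ multiplies the off-diagonals of `C` (equivalently: every
branch is multiplied by λ and each terminal branch is stretched by
`(1−λ)·depth` so the diagonal is preserved); λ = 1 is Brownian motion,
λ = 0 a star phylogeny.  λ is restricted to [0, 1]; values above 1 are not
meaningful for most trees and are rejected.

Composite supertrees have no meaningful branch lengths, so Nee's method is
provided: node height above the tips is `ln(number of descendant tips)`,
making the tree ultrametric with depth `ln n`.  The literature names this
method without printing a formula; the log-tip-count convention used by
Mesquite is adopted and is switchable by supplying your own lengths.  Path
lengths stay in the tree's native units throughout — nothing is rescaled to
unit height behind the caller's back.

Polytomies (unavoidable in composite trees) are resolved deterministically
left-to-right with zero-length internal branches before contrasts are
computed.  A zero-variance contrast with equal descendant values gets
variance `min positive branch-sum × 1e−6`; with unequal values it is an
error.  Missing branch lengths are carried as `None` and rejected by name,
never silently zeroed.

## PGLS with ML λ

The Gaussian log-likelihood is profiled over λ: β and σ² are maximized
analytically at each λ (Cholesky whitening + least squares), and λ is found
by a 41-point grid over [0, 1] followed by bounded scalar refinement
(tolerance 1e−8), with the endpoints always checked; ties at a boundary
resolve to the boundary.  The grid-then-refine scheme guards against local
bumps in the profile; a test asserts the optimum beats a 1001-point scan.

Inference follows the caper conventions: SEs use `σ̂² = RSS/(n−k)`, t-tests
have `df = n − k`, and `R² = 1 − RSS/RSS₀` with the intercept-only RSS₀
evaluated at the same λ̂.  AIC counts `k + 2` parameters (coefficients, σ²,
λ).  Type-3 ("marginal") tests are Wald F-statistics — each term against
the model containing all others — with denominator df `n − k`; for a
single-coefficient term F = t² exactly.  Per-group slopes from interaction
fits are linear combinations of coefficients with the XY group as the
reference level (slope(ZW) = b_trait + b_interaction), SEs from the
coefficient covariance, and t-based CIs.

The quadratic check refits linear and quadratic models each with its own ML
λ̂ (matching an AIC comparison; fixing λ across the pair is a documented
alternative) and reports ΔAIC = AIC(quad) − AIC(lin) plus a 1-df LRT.

The power analysis simulates `y* = effect·x* + ε` on a fixed,
phylogenetically transformed predictor `x*` (independent contrasts in the
pipeline).  For correlation-type effects x* is z-scored and
`ε ~ N(0, 1 − effect²)`, so the standardized slope equals the target effect
size; for group-difference (Cohen's d) effects with a 0/1 predictor,
`ε ~ N(0, 1)`.  Power is the rejection fraction with a binomial SE.

## Trait table conventions

Bias metrics are `log10(male/female)` (antisymmetric under sex swap), sex
ratios are proportions of males, and species with several population
records get the arithmetic mean per metric.  A female rate of zero makes the
metric missing with a warning rather than ±∞.  Standardization uses the
sample SD (n−1).  z-scores are computed on each model's complete-case
subset by default — this makes a group coefficient an exact Cohen's d for
that model's species — with a full-table scope available for sensitivity
checks.  Outliers are species more than 3 group-SDs from their GSD group's
mean of the standardized predictor; groups with fewer than 3 members are
never flagged.

## Path analysis

The candidate set comprises eight DAGs over {GSD, JMB, AMB, MAT, ASR}.  All
contain GSD→AMB and the three demographic effects on ASR; ".b" models add
the direct GSD→ASR edge; models 2/3/4 add GSD→JMB, GSD→MAT, or both.

Basis sets differ by flavor.  The hardenberg flavor tests every non-adjacent
pair (k = 10 − edges).  The santos flavor treats exogenous–exogenous pairs
as freely correlated and excludes them from the basis set; this is the only
reading consistent with both the published claim counts and degrees of
freedom of the two flavors (k = 5 yet df = 4 ⇒ 2 claims for the
best-supported model).  A consequence worth knowing: adding an edge can
*create* santos claims by making a vertex endogenous, so Fisher's C is
guaranteed monotone under edge addition only when the claim sets are
actually nested (always true in the hardenberg flavor).

Each claim is tested by regressing the pair member later in the model's
causal order (deterministic topological order, alphabetical tie-break) on
the other member plus the union of both members' parents.  The santos flavor
runs this as an ordinary regression, with intercept, on transformed data:
per variable, λ̂ from an intercept-only PGLS, the tree rescaled by λ̂, and
standardized independent contrasts on that tree, aligned across variables
by contrast node (a through-origin switch exists for purists).  The
hardenberg flavor runs the same regression as a PGLS with its own ML λ on
the raw data.  GSD enters numerically (XY = 0, ZW = 1, then z-scored), as
any contrast/GLS engine implicitly requires.

Fit: Fisher's `C = −2 Σ ln pᵢ`, df = 2k; a claim p of exactly 0 yields an
infinite C reported as certain rejection.  Ranking uses
`C + 2qn/(n−1−q)` with flavor-specific q: edges + vertices (hardenberg
CICc), or per-regression coefficients including intercepts plus one
residual variance per endogenous variable (santos AICc).  Both counts
reproduce the published criterion values from the printed C statistics.

Standardized path coefficients (`b·SD(parent)/SD(child)` on the flavor's
analysis data) get percentile CIs from a residual bootstrap within each
component regression — resampling species would break the phylogenetic
alignment — with 500 iterations by default, seeded; the hardenberg λ̂ is
held fixed across bootstrap refits.  Singular replicates are dropped and
counted.

Nested models are compared by a Gaussian path-model LRT on the transformed
data: ML log-likelihood via the model-implied covariance (saturated means,
saturated exogenous covariances, independent residuals — OLS per endogenous
regression is exactly ML for recursive models).  The df is the
free-parameter difference, which equals the edge difference when the
exogenous set is unchanged but differs when an added edge makes a vertex
endogenous; the free-parameter convention is the one under which the LRT
statistic is χ²-calibrated (verified by simulation against the saturated
model) and reproduces a 1-df test for every published pairwise comparison.

## Mk model and stochastic maps

The binary XY/ZW character evolves under
`Q = [[−q01, q01], [q10, −q10]]` with the closed-form 2-state transition
probabilities.  The pruning likelihood uses per-node rescaling; the root
prior is equal (0.5/0.5), the default of the reconstruction tool this
mirrors, and is configurable.  ER optimizes one rate by bounded scalar
search on the log scale; ARD uses L-BFGS-B from three starts.  Single-state
data put the rates at the zero boundary with a warning (logL = ln prior).

Stochastic maps sample node states from their conditional distributions
(pruning pass, root draw, then child-given-parent draws) and fill in branch
histories conditional on both endpoints by uniformization — the jump count
is drawn from its exact conditional distribution and the jump chain is
bridged by forward-filtering — which is exact and free of rejection bias.
Transitions are counted per direction per map.  Fitch parsimony provides a
lower-bound oracle for the mean count.  The fitted rates, log-likelihoods
and map summaries were cross-checked against the standard R implementation
during development and agree to printed precision.

## Synthetic generator

`simulate_tree` is a Yule process conditioned on n tips, rescaled to unit
height.  The binary character is simulated forward along branches with the
realized transition count recorded as ground truth; default rates are
calibrated to the rare-transition regime (~17 realized changes on a 453-tip
tree, asymmetric toward ZW→XY with a ZW root).  Continuous traits are built
from the m1.b path structure: each endogenous variable is the
coefficient-weighted sum of its parents plus λ-structured residual noise
(`√λ·BM + √(1−λ)·iid`, variance split so the total variance is ~1, floor
0.05), so the configured coefficients (defaults −0.5, −0.2, −0.25, −0.2,
0.6, echoing the fitted path-coefficient magnitudes) are on the
standardized scale.  Latent traits are mapped to natural-looking columns
(sex ratios as proportions around 0.5, biases on a log-ratio scale) by
monotone linear maps, which re-standardization undoes.

Missingness is MCAR per variable at the study's marginal rates, with a
fully observed block of ~21% of species emulating well-studied taxa; this
reproduces both the per-variable sample sizes and the ~95-species
complete-case subset.  The generator does **not** emulate state-dependent
diversification, non-Gaussian trait distributions, measurement error,
phylogenetically clustered missingness, or taxon-specific effect
heterogeneity — passing recovery tests therefore demonstrates estimator
correctness under the assumed model, not robustness to those violations.
All randomness flows from one numpy PCG64 generator per seed.

## Problem sizes used in the test suite

Distributional checks run at the sizes that make them informative yet
routine to rerun: claim-p uniformity at 1000 replicates of 95-tip datasets;
LRT null calibration at 500 replicates; type-3 interaction size at 500
replicates of 100-tip data; coefficient-recovery and model-selection checks
at 100 full-size (453-tip) replicates with 200 bootstrap iterations; λ
recovery at 30–100 replicates.  These sizes are the package's reference
conditions and are stated here so that reruns scale them knowingly.

## Known limitations

* λ is constrained to [0, 1]; no REML, no Ornstein–Uhlenbeck or other
  correlation structures, no measurement-error models.
* The Mk machinery is strictly binary; no hidden-rate or >2-state models.
* The santos flavor's per-variable transformation can distort the scale of
  coefficients whose parent and child were transformed under different λ̂;
  the hardenberg flavor is the recommended estimator when coefficient
  magnitudes matter.
* d-separation p-values are asymptotic; with very small complete-case
  subsets the Fisher's C test is approximate.
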