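# Methods

## Model

Each gene is modelled independently as a Gaussian process over the tissue
plane with an exponential covariance and a nugget:

    y ~ N(Xβ, σ² R(l) + τ² I),   R_ij = exp(−‖sᵢ − sⱼ‖ / l).

σ² is the spatially structured variance, τ² the nonspatial (technical +
unstructured biological) variance, and l the length scale governing how fast
spatial correlation decays. The exponential kernel is used in preference to
the squared-exponential because expression correlation in tissue decays
slowly with distance; its heavier tail fits SRT data better. The response is
assumed continuous and roughly Gaussian, which is why the pipeline feeds the
model log-transformed normalized counts (or binomial deviance residuals)
rather than raw UMIs.

Coordinates are shifted and divided by the largest axis range so the longer
axis spans [0, 1] (aspect ratio preserved; the kernel is isotropic). All
length scales are reported in these units, so l ≈ 0.1 means correlation
decaying over a tenth of the tissue width. Exact duplicate locations are
perturbed by a deterministic jitter of 1e−6 (the factorization requires
distinct sites).

## Nearest-neighbor (Vecchia) likelihood

The dense likelihood is O(N³). We factorize the joint density of the
*marginal* covariance Σ = σ²R + τ²I along a max-min distance ordering,
conditioning each location on its m nearest previously-ordered neighbors:

    log L ≈ Σᵢ log N(r_{(i)} ; Bᵢ r_{nb(i)}, Fᵢ),   r = y − Xβ,

with Bᵢ = Σ_{i,nb} Σ_{nb,nb}⁻¹ and Fᵢ = Σ_{ii} − Bᵢ Σ_{nb,i}. Each term costs
one m×m solve, so an evaluation is exactly N batched solves — O(N·m³) — and
exact when m ≥ N−1. Conditioning is applied to the marginal covariance
(response-level Vecchia), not to a latent-field-plus-nugget decomposition.
The ordering is the exact greedy max-min: start at the spot nearest the
centroid, then repeatedly add the spot maximizing its minimum distance to
those already ordered (O(N²), deterministic, ties to the lowest index). A
cheap coordinate-sum ordering is available as a fallback. Orderings and
neighbor sets depend only on the geometry and are computed once per dataset,
then shared by every gene — results are bit-identical to rebuilding per gene.

Default m = 10 neighbors. Neighbor caches are padded to fixed width with
infinite distances so that all N conditional factors are computed in one
batched triangular solve; padded slots contribute zero weight exactly.

## Fitting

The likelihood is maximized over the decay φ = 1/l and noise ratio
α = τ²/σ² on the log scale. At each candidate (φ, α): the Vecchia factors
whiten y and X, β is the exact generalized-least-squares solution in the
whitened frame, and σ² is profiled analytically as RSS/N (a joint search
including log σ² is available via `profile_sigma2=False`; the two agree to
within optimizer tolerance). L-BFGS-B is run from three initializations
(l at 1/4, 1/2 and 1 times the maximum pairwise distance; α = 1), with
bounds l ∈ [d_max/500, 10·d_max] and α ∈ [1e−6, 1e6], relative tolerance
1e−6, at most 200 evaluations per start; the best optimum wins.
Non-convergence returns the best point found, flagged. Constant responses
are rejected (the spatial model is degenerate; the null linear model is the
appropriate fit).

The null model (σ² = 0) is the ordinary linear model with ML variance
τ̂² = RSS/N. The test statistic is LR = 2(ℓ_full − ℓ_null) against χ²(2 df)
(two extra parameters: σ², l). Because σ² = 0 sits on the boundary of the
parameter space, the 2-df reference is conservative — null rejection rates
run below nominal, which the simulation study confirms. Small negative LR
values can occur because the Vecchia likelihood is not exactly nested in
the linear model's; they are reported as-is (ranked below all positive LRs)
with p evaluated at max(LR, 0).

Across genes: Benjamini–Hochberg adjustment, ranking by decreasing LR (ties
broken by higher propSV, then gene id), effect size propSV = σ̂²/(σ̂²+τ̂²).
With domain labels supplied, X becomes intercept + one-hot indicators
(lexicographically first level dropped), so domain-wise mean shifts are
absorbed and the test targets residual spatial variation within domains.
Multi-sample datasets are combined by averaging within-sample ranks; genes
absent from some samples are placed after all complete genes, ordered by the
mean of their available ranks.

## Preprocessing

Gene filter: keep genes with ≥ `min_count` UMIs in ≥ ceil(`min_prop_spots`·N)
spots (defaults 3 and 0.5%, appropriate for Visium-scale data; sparser
platforms need lower thresholds) and drop genes whose ids start with a
mitochondrial prefix ("MT-"/"mt-", configurable). Spot-level QC is a simple
threshold filter on library size and genes detected; its defaults keep
everything because sensible thresholds are dataset-specific — inspect the QC
metric distributions before choosing them.

Logcounts: size factor per spot = library size / mean library size, value =
log2(count/size factor + 1). Deviance residuals: per-gene binomial null
model with pooled rate π̂ = Σy/Σn against spot totals n, the standard signed
square-root deviance form with 0·log 0 ≡ 0.

## Baselines

- **HVGs**: per-gene mean and variance of logcounts across spots; a lowess
  trend (span 0.3) of variance on mean; score = variance above trend.
  Ignores coordinates entirely.
- **Deviance**: genes ranked by total squared binomial deviance residuals.
  Also coordinate-free.
- **Moran's I**: weights w_ij = 1/d_ij², optionally truncated to each spot's
  k nearest neighbors (k = 36 mirrors a common convention) and symmetrized.
  Untruncated is the default.

## Simulation framework

Spots on a regular square lattice scaled to the unit frame (a square lattice
is an adequate stand-in for the hexagonal Visium grid at these densities).
Each SVG gene gets a circular hotspot of radius `radius_frac` (fraction of
frame width) placed uniformly subject to containment; in-mask mean is
mu_low + strength_frac·(mu_high − mu_low). Values are drawn as
Normal(mean, var) directly on the logcount scale and independently zeroed at
the region's sparsity rate; noise genes use the background distribution
everywhere. Defaults mu_high = 4, mu_low = 1, var = 1, sparsity 0.3 (hotspot)
/ 0.6 (background) describe a strong marker gene against a sparse background;
they are deliberate, configurable stand-ins — real calibration would estimate
them from a reference tissue. Note the sparsity contrast is part of the
hotspot signal at every strength, so even low-strength scenarios retain some
detectable structure at large radii.

The scenario grid crosses radius ∈ {0.25, 0.125, 0.025} with strength ∈
{1, 1/3, 1/10}. The ablation study shuffles the coordinates of a random
subset of spots (fraction 0–1); the null study applies one global coordinate
permutation to all genes (per-gene permutation is available). TPR/FPR are
computed against the generative labels at nominal unadjusted p-value
thresholds (adjusted optional).

What the generator does *not* emulate: count-level noise (values are
generated on the log scale directly), hexagonal geometry, spatial domains
with irregular shapes, gene–gene correlation, and platform artifacts such as
spot-to-spot bleed. Passing simulation tests therefore demonstrates
correctness of the inference machinery and qualitative error-control/power
behavior, not calibrated performance on any real tissue.

## Problem sizes used by the test suite

The simulation studies run at a reduced scale chosen to keep the full suite
fast while leaving each rate estimable: the error-control and null studies
use 1000 spots with 20 SVG + 200 noise genes; the power grid uses 20 SVG +
30 noise genes per scenario cell; the ablation study refits the 20 SVG genes
at shuffle fractions {0, 0.3, 0.6, 0.9, 1}; parameter recovery uses 50
replicates at n = 500; scaling uses n ∈ {200, 500, 1000, 2000}.

## Numerical notes and limitations

- Response-level Vecchia with m = 10 is accurate (relative log-likelihood
  error ~1e−3–1e−2) for data compatible with the fitted parameters and
  length scales inside the domain (l ≲ 0.5). Accuracy degrades when the
  nugget dominates (τ²/σ² ≳ 10) *and* the length scale exceeds the domain
  width — a regime where the spatial signal is unidentifiable anyway; the
  error is conservative there (it lowers the spatial model's likelihood).
- Non-positive conditional variances (possible with near-duplicate sites)
  raise immediately with the offending index rather than returning NaN.
- The χ²(2) p-values are approximate and conservative at the boundary; the
  package reports them as the paper's convention does, and ranking by LR is
  unaffected.
- Estimates of l near the box bounds (l = 10·d_max or d_max/500) indicate an
  unidentified length scale (signal too smooth or too fine for the sampling
  density); σ² and the LR remain meaningful.
- Bootstrap standard errors, non-exponential kernels, anisotropy and 3-D
  coordinates are out of scope.
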