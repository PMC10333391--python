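# svgnn

Identification of **spatially variable genes (SVGs)** in spatially-resolved
transcriptomics (Visium, Slide-seq, ST, seqFISH, ...) using per-gene
**nearest-neighbor Gaussian process (NNGP)** models with a likelihood-ratio
test of the spatial variance component.

## The model

For each gene, let *y* = (y₁, …, y_N) be normalized, log-transformed
expression at spatial locations *s* = (s₁, …, s_N) scaled into the unit
frame. The model is

    y ~ N(Xβ, σ² R(l) + τ² I),     R_ij = exp(−‖sᵢ − sⱼ‖ / l)

an exponential-kernel Gaussian process with spatial variance σ², gene-specific
length scale *l*, and nugget (nonspatial variance) τ². The design matrix X is
an intercept by default, or intercept + spatial-domain indicators to test for
variation *within* known domains.

The exact Gaussian likelihood costs O(N³). svgnn uses a nearest-neighbor
(Vecchia) factorization of the marginal covariance: locations are taken in a
max-min distance ordering and each conditions on its m = 10 nearest
previously-ordered neighbors, giving O(N·m³) likelihood evaluations — linear
in the number of spots. The ordering and neighbor sets are computed once and
reused across all genes.

Each gene is tested with

    LR = 2·(log L_spatial − log L_linear),     H₀: σ² = 0,

compared against χ² with 2 degrees of freedom; p-values are
Benjamini–Hochberg adjusted across genes, genes are ranked by decreasing LR,
and the effect size is the proportion of spatial variance
propSV = σ²/(σ² + τ²). Nonspatial baselines (highly variable genes, binomial
deviance residuals) and Moran's I with inverse-squared-distance weights are
included, along with a hotspot simulation framework for power/error studies.

## Worked example

```python
import numpy as np
from svgnn import SimScenario, generate, run_svg, results_to_frame, significant_svgs

# 400 lattice spots; 3 hotspot genes (radius 0.25, full strength) + 12 noise genes
scn = SimScenario(n_spots=400, radius_frac=0.25, strength_frac=1.0,
                  n_svg=3, n_noise=12, seed=42)
ds = generate(scn)
results = run_svg(ds.mat, ds.geom)
print(results_to_frame(results).head(5))
print([r.gene_id for r in significant_svgs(results, 0.05)])
```

prints (abridged):

```
   gene_id  sigma2      tau2       l  prop_sv  lr_stat      pval      padj  rank
  svg_0001   1.243     1.032  0.2084   0.5464    143.4  7.21e-32 1.081e-30     1
  svg_0000  0.7624     1.144  0.2277   0.3999    113.1 2.788e-25 2.091e-24     2
  svg_0002  0.7649     1.449   1.407   0.3455    80.69 3.014e-18 1.507e-17     3
noise_0003  0.5172 5.172e-07 0.01755        1    2.082     0.353         1     4
noise_0005 0.04125    0.5743 0.09386  0.06701    1.915    0.3839     1         5

significant at FDR 0.05: ['svg_0001', 'svg_0000', 'svg_0002']
```

The three simulated hotspot genes are recovered with large LR statistics,
fitted length scales near the hotspot size, and propSV ≈ 0.35–0.55; all noise
genes have adjusted p ≈ 1. Note `noise_0003`: a near-zero nugget estimate can
push propSV to 1, but the LR statistic (and hence rank and p-value) stays
small — rankings are driven by LR, not propSV.

The same pipeline is available from the shell:

```sh
svgnn simulate --scenario medium-medium --n-svg 100 --n-noise 900 --n-spots 2000 --seed 1 --out sim/
svgnn run --counts counts.tsv --coords coords.tsv --out results.tsv
svgnn baseline --method moran --counts counts.tsv --coords coords.tsv --out moran.tsv
svgnn evaluate --results results.tsv --truth sim/truth.tsv --thresholds 0.01,0.05,0.1
svgnn combine --results s1.tsv --results s2.tsv --out combined.tsv
```

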