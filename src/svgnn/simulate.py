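"""Synthetic Visium-like data and the evaluation harness.

Spots sit on a regular 2-D lattice in the unit frame. Spatially variable
genes carry a circular hotspot of elevated mean expression whose radius (as
a fraction of the frame width) sets the length scale of the signal and whose
mean shift (a fraction of the full high-low contrast) sets its strength.
Values are generated directly on the logcount scale as Gaussians and then
zeroed at the region's sparsity rate, emulating the zero inflation of
spot-level expression; noise genes draw from the background distribution
everywhere. The harness adds coordinate-shuffling ablation, permutation
nulls, and TPR/FPR evaluation against the generative truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nngp import SpotGeometry
from .preprocess import ExpressionMatrix
from .ranking import GeneFitResult

__all__ = [
    "SimScenario", "SimDataset", "generate", "ablate", "null_permute",
    "evaluate", "RADIUS_GRID", "STRENGTH_GRID",
]

# scenario grids: hotspot radius as a fraction of the frame width, and mean
# shift as a fraction of the full high-low contrast
RADIUS_GRID = (0.25, 0.125, 0.025)
STRENGTH_GRID = (1.0, 1.0 / 3.0, 0.1)


@dataclass
class SimScenario:
    """Generator settings for one hotspot scenario.

    The default high/low means, variances and sparsity rates describe a
    strongly expressed marker inside its domain against a sparse low
    background, on the logcount scale.
    """

    n_spots: int = 1000
    radius_frac: float = 0.125
    strength_frac: float = 1.0 / 3.0
    n_svg: int = 100
    n_noise: int = 900
    mu_high: float = 4.0
    mu_low: float = 1.0
    var_high: float = 1.0
    var_low: float = 1.0
    sparsity_high: float = 0.3
    sparsity_low: float = 0.6
    fixed_center: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.radius_frac < 0.5:
            raise ValueError("radius_frac must be in (0, 0.5)")
        if not 0.0 < self.strength_frac <= 1.0:
            raise ValueError("strength_frac must be in (0, 1]")
        for s in (self.sparsity_high, self.sparsity_low):
            if not 0.0 <= s < 1.0:
                raise ValueError("sparsity must be in [0, 1)")
        if self.n_svg + self.n_noise < 1:
            raise ValueError("need at least one gene")


@dataclass
class SimDataset:
    """Generated expression (logcount scale), geometry and gene-level truth."""

    mat: ExpressionMatrix
    geom: SpotGeometry
    truth: pd.DataFrame  # gene_id, label in {svg, noise}, center_x, center_y, radius

    @property
    def svg_ids(self) -> list[str]:
        return list(self.truth.loc[self.truth.label == "svg", "gene_id"])

    @property
    def noise_ids(self) -> list[str]:
        return list(self.truth.loc[self.truth.label == "noise", "gene_id"])


def _lattice(n_spots: int) -> np.ndarray:
    """First n points of the smallest square lattice covering n_spots,
    scaled to the unit frame."""
    side = int(np.ceil(np.sqrt(n_spots)))
    xs, ys = np.meshgrid(np.arange(side), np.arange(side))
    pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    pts = pts[:n_spots] / (side - 1)
    return pts


def generate(scn: SimScenario) -> SimDataset:
    """Draw one synthetic dataset under a hotspot scenario.

    For each SVG gene a circular mask of radius ``radius_frac`` (unit-frame
    width) is placed uniformly at random subject to full containment (or at
    ``fixed_center``); in-mask mean is
    mu_low + strength_frac * (mu_high - mu_low), out-of-mask mean is mu_low.
    Values are Normal(mean, var) with independent zeroing at the region's
    sparsity rate. Noise genes use the out-of-mask distribution everywhere.
    """
    rng = np.random.default_rng(scn.seed)
    coords = _lattice(scn.n_spots)
    geom = SpotGeometry(coords, scale_factor=1.0)
    n = scn.n_spots
    r = scn.radius_frac
    if r >= 0.5:
        raise ValueError("radius too large to fit inside the unit frame")
    mu_in = scn.mu_low + scn.strength_frac * (scn.mu_high - scn.mu_low)

    width = coords[:, 0].max()
    height = coords[:, 1].max()
    if 2 * r > min(width, height):
        raise ValueError("radius too large to fit a circle inside the frame")

    g_total = scn.n_svg + scn.n_noise
    values = np.empty((g_total, n))
    rows = []
    for g in range(scn.n_svg):
        if scn.fixed_center is not None:
            cx, cy = scn.fixed_center
        else:
            cx = rng.uniform(r, width - r)
            cy = rng.uniform(r, height - r)
        inside = (coords[:, 0] - cx) ** 2 + (coords[:, 1] - cy) ** 2 <= r ** 2
        mean = np.where(inside, mu_in, scn.mu_low)
        sd = np.sqrt(np.where(inside, scn.var_high, scn.var_low))
        vals = rng.normal(mean, sd)
        sparsity = np.where(inside, scn.sparsity_high, scn.sparsity_low)
        vals[rng.random(n) < sparsity] = 0.0
        values[g] = vals
        rows.append({"gene_id": f"svg_{g:04d}", "label": "svg",
                     "center_x": cx, "center_y": cy, "radius": r})
    for g in range(scn.n_noise):
        vals = rng.normal(scn.mu_low, np.sqrt(scn.var_low), size=n)
        vals[rng.random(n) < scn.sparsity_low] = 0.0
        values[scn.n_svg + g] = vals
        rows.append({"gene_id": f"noise_{g:04d}", "label": "noise",
                     "center_x": np.nan, "center_y": np.nan, "radius": np.nan})

    gene_ids = [row["gene_id"] for row in rows]
    spot_ids = [f"spot_{i:05d}" for i in range(n)]
    mat = ExpressionMatrix(values, gene_ids, spot_ids, layer_tag="logcounts")
    return SimDataset(mat=mat, geom=geom, truth=pd.DataFrame(rows))


def ablate(ds: SimDataset, shuffle_frac: float, seed: int = 0) -> SimDataset:
    """Shuffle the coordinates of a random subset of spots.

    A uniformly chosen floor(shuffle_frac * N) subset has its coordinates
    permuted among the subset; expression values are untouched. At
    shuffle_frac = 1 this is a full coordinate permutation.
    """
    if not 0.0 <= shuffle_frac <= 1.0:
        raise ValueError("shuffle_frac must be in [0, 1]")
    n = ds.geom.n_spots
    k = int(np.floor(shuffle_frac * n))
    if k < 2:
        return SimDataset(ds.mat, SpotGeometry(ds.geom.coords.copy(),
                                               ds.geom.scale_factor), ds.truth)
    rng = np.random.default_rng(seed)
    subset = rng.choice(n, size=k, replace=False)
    perm = rng.permutation(k)
    coords = ds.geom.coords.copy()
    coords[subset] = coords[subset[perm]]
    return SimDataset(ds.mat, SpotGeometry(coords, ds.geom.scale_factor), ds.truth)


def null_permute(
    mat: ExpressionMatrix, geom: SpotGeometry, seed: int = 0
) -> tuple[ExpressionMatrix, SpotGeometry]:
    """Permute the spot coordinates once, globally, to destroy all spatial
    correlation while leaving every gene's marginal distribution intact."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(geom.n_spots)
    return mat, SpotGeometry(geom.coords[perm], geom.scale_factor)


def evaluate(
    results: list[GeneFitResult],
    truth: pd.DataFrame,
    thresholds: list[float] = (0.01, 0.05, 0.1),
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """TPR and FPR against generative truth at nominal p-value thresholds.

    TPR = fraction of true SVGs with p <= t; FPR = fraction of noise genes
    with p <= t. Unadjusted p-values by default.
    """
    labels = dict(zip(truth.gene_id, truth.label))
    missing = [r.gene_id for r in results if r.gene_id not in labels]
    if missing:
        raise ValueError(f"results contain genes absent from truth: {missing[:5]}")
    pvals = {r.gene_id: (r.padj if use_adjusted else r.pval) for r in results}
    svg_p = np.array([p for g, p in pvals.items() if labels[g] == "svg"])
    noise_p = np.array([p for g, p in pvals.items() if labels[g] == "noise"])
    rows = []
    for t in thresholds:
        tpr = float(np.mean(svg_p <= t)) if svg_p.size else np.nan
        fpr = float(np.mean(noise_p <= t)) if noise_p.size else np.nan
        rows.append({"threshold": t, "tpr": tpr, "fpr": fpr})
    return pd.DataFrame(rows)
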