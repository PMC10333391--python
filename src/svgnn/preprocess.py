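"""Quality control and transformation of raw spot-level counts.

Turns a genes-by-spots UMI count matrix into the per-gene response vectors the
spatial models consume: filtering of low-expressed and mitochondrial genes,
library-size-normalized log2 counts ("logcounts"), and binomial deviance
residuals as a count-based alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LAYER_TAGS = ("counts", "logcounts", "deviance_residuals")

# Default gene filter: >= 3 UMI counts in >= 0.5% of spots, drop MT- genes.
# Appropriate for Visium-scale data; adjust for sparser platforms.
DEFAULT_MIN_COUNT = 3
DEFAULT_MIN_PROP_SPOTS = 0.005
DEFAULT_MITO_PREFIXES = ("MT-", "mt-")


@dataclass
class ExpressionMatrix:
    """Genes-by-spots expression values with identifiers.

    ``values`` is a dense [G x N] array. The ``layer_tag`` records which
    transformation has been applied; raw input must be tagged ``counts`` and
    hold non-negative integers.
    """

    values: np.ndarray
    gene_ids: list[str]
    spot_ids: list[str]
    layer_tag: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = list(self.gene_ids)
        self.spot_ids = list(self.spot_ids)
        if self.values.ndim != 2:
            raise ValueError("expression values must be 2-D [genes x spots]")
        g, n = self.values.shape
        if g != len(self.gene_ids) or n != len(self.spot_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids x {len(self.spot_ids)} spot ids"
            )
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicated gene_ids")
        if self.layer_tag not in LAYER_TAGS:
            raise ValueError(f"unknown layer_tag {self.layer_tag!r}")
        if self.layer_tag == "counts":
            if np.any(self.values < 0):
                raise ValueError("counts must be non-negative")
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts layer must be integer-valued")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return ExpressionMatrix(
            self.values[idx],
            [self.gene_ids[i] for i in idx],
            self.spot_ids,
            self.layer_tag,
        )

    def subset_spots(self, keep: np.ndarray) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return ExpressionMatrix(
            self.values[:, idx],
            self.gene_ids,
            [self.spot_ids[i] for i in idx],
            self.layer_tag,
        )


@dataclass
class FilterSpec:
    """Gene-filter thresholds: keep genes with ``count >= min_count`` in at
    least ``ceil(min_prop_spots * N)`` spots; optionally drop genes whose id
    starts with a mitochondrial prefix."""

    min_count: int = DEFAULT_MIN_COUNT
    min_prop_spots: float = DEFAULT_MIN_PROP_SPOTS
    drop_mito: bool = True
    mito_prefixes: tuple[str, ...] = DEFAULT_MITO_PREFIXES

    def __post_init__(self) -> None:
        if self.min_count < 0:
            raise ValueError("min_count must be >= 0")
        if not 0.0 <= self.min_prop_spots <= 1.0:
            raise ValueError("min_prop_spots must be in [0, 1]")


def filter_genes(mat: ExpressionMatrix, spec: FilterSpec | None = None) -> ExpressionMatrix:
    """Remove low-expressed and (optionally) mitochondrial genes.

    A gene passes when it has at least ``spec.min_count`` counts in at least
    ``ceil(spec.min_prop_spots * N)`` spots (boundary counts as passing).
    Gene order is preserved. Raises ``ValueError`` if nothing passes.
    """
    if spec is None:
        spec = FilterSpec()
    if mat.layer_tag != "counts":
        raise ValueError("filter_genes expects the counts layer")
    n_required = int(np.ceil(spec.min_prop_spots * mat.n_spots))
    n_spots_passing = np.sum(mat.values >= spec.min_count, axis=1)
    keep = n_spots_passing >= n_required
    if spec.drop_mito:
        is_mito = np.array(
            [any(g.startswith(p) for p in spec.mito_prefixes) for g in mat.gene_ids]
        )
        keep &= ~is_mito
    if not keep.any():
        raise ValueError("no genes pass filter")
    return mat.subset_genes(keep)


def filter_spots(
    mat: ExpressionMatrix,
    min_library_size: int = 0,
    min_genes_detected: int = 0,
) -> ExpressionMatrix:
    """Spot-level QC: drop spots with small library size or few detected genes.

    Defaults keep everything; thresholds are dataset-specific and should be
    chosen by inspecting the QC metric distributions.
    """
    if mat.layer_tag != "counts":
        raise ValueError("filter_spots expects the counts layer")
    libsize = mat.values.sum(axis=0)
    detected = np.sum(mat.values > 0, axis=0)
    keep = (libsize >= min_library_size) & (detected >= min_genes_detected)
    if not keep.any():
        raise ValueError("no spots pass filter")
    return mat.subset_spots(keep)


def logcounts(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Library-size-normalized log2 counts.

    Size factor per spot = library size / mean library size (so factors
    average to 1); value = log2(count / size_factor + 1).
    """
    if mat.layer_tag != "counts":
        raise ValueError("logcounts expects the counts layer")
    libsize = mat.values.sum(axis=0)
    zero = np.flatnonzero(libsize == 0)
    if zero.size:
        raise ValueError(
            f"spot(s) with zero library size: {[mat.spot_ids[i] for i in zero[:5]]}"
        )
    size_factors = libsize / libsize.mean()
    vals = np.log2(mat.values / size_factors[None, :] + 1.0)
    return ExpressionMatrix(vals, mat.gene_ids, mat.spot_ids, "logcounts")


def binomial_deviance_residuals(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Deviance residuals of the per-gene null binomial model.

    For gene g at spot i with spot total n_i and pooled rate
    pi_g = sum_i y_gi / sum_i n_i, the residual is

        sign(y - n*pi) * sqrt(2 [ y log(y/(n pi)) + (n-y) log((n-y)/(n-n pi)) ])

    with the 0*log(0) terms taken as 0. Genes with zero total count get all-zero
    residuals.
    """
    if mat.layer_tag != "counts":
        raise ValueError("binomial_deviance_residuals expects the counts layer")
    y = mat.values
    n = y.sum(axis=0)
    if np.any(n == 0):
        bad = np.flatnonzero(n == 0)
        raise ValueError(
            f"spot(s) with zero total count: {[mat.spot_ids[i] for i in bad[:5]]}"
        )
    pi = y.sum(axis=1) / n.sum()  # pooled per-gene rate
    mu = pi[:, None] * n[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(n[None, :] - y > 0,
                      (n[None, :] - y) * np.log((n[None, :] - y) / (n[None, :] - mu)),
                      0.0)
    dev = 2.0 * (t1 + t2)
    # tiny negative values from rounding
    dev = np.clip(dev, 0.0, None)
    res = np.sign(y - mu) * np.sqrt(dev)
    res[pi == 0.0] = 0.0
    return ExpressionMatrix(res, mat.gene_ids, mat.spot_ids, "deviance_residuals")
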