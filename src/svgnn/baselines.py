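"""Baseline gene rankers: HVGs, binomial deviance, and Moran's I.

HVGs and deviance residuals ignore the coordinates entirely; Moran's I is the
classical spatial-autocorrelation statistic with inverse-squared-distance
weights. All three return rankings where a higher score means a better rank.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .nngp import SpotGeometry
from .preprocess import ExpressionMatrix, binomial_deviance_residuals

__all__ = ["BaselineRanking", "hvg_rank", "morans_i", "morans_rank", "deviance_rank"]


@dataclass
class BaselineRanking:
    gene_id: str
    score: float
    rank: int


def _rank_by_score(gene_ids: list[str], scores: np.ndarray) -> list[BaselineRanking]:
    """Rank by decreasing score; NaN scores last; ties by gene_id."""
    order = sorted(
        range(len(gene_ids)),
        key=lambda i: (-(scores[i] if np.isfinite(scores[i]) else -np.inf),
                       gene_ids[i]),
    )
    out = [None] * len(gene_ids)
    for rank, i in enumerate(order, start=1):
        out[i] = BaselineRanking(gene_ids[i], float(scores[i]), rank)
    return sorted(out, key=lambda r: r.rank)


def hvg_rank(mat: ExpressionMatrix, span: float = 0.3) -> list[BaselineRanking]:
    """Highly variable genes: variance in excess of a mean-variance trend.

    A lowess trend (span = fraction of genes in each local fit) is fitted to
    per-gene variance against per-gene mean of the logcounts; the score is
    the residual variance above the trend. No spatial information is used.
    """
    if mat.layer_tag != "logcounts":
        raise ValueError("hvg_rank expects the logcounts layer")
    if mat.n_genes < 10:
        raise ValueError("need at least 10 genes to fit a mean-variance trend")
    means = mat.values.mean(axis=1)
    variances = mat.values.var(axis=1, ddof=1)
    fitted = lowess(variances, means, frac=span, return_sorted=False)
    scores = variances - fitted
    return _rank_by_score(mat.gene_ids, scores)


def _weight_matrix(geom: SpotGeometry, truncate_k: int | None) -> np.ndarray:
    d = geom.pairwise_distances()
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    if np.any(d[off] == 0.0):
        raise ValueError("coincident spots give infinite weights; jitter upstream")
    w = np.zeros_like(d)
    w[off] = 1.0 / d[off] ** 2
    if truncate_k is not None:
        nn = NearestNeighbors(n_neighbors=min(truncate_k + 1, n)).fit(geom.coords)
        _, idx = nn.kneighbors(geom.coords)
        mask = np.zeros_like(w, dtype=bool)
        rows = np.repeat(np.arange(n), idx.shape[1] - 1)
        mask[rows, idx[:, 1:].ravel()] = True
        w = np.where(mask, w, 0.0)
        w = 0.5 * (w + w.T)  # keep the weight matrix symmetric
    return w


def morans_i(
    y: np.ndarray, geom: SpotGeometry, truncate_k: int | None = None
) -> float:
    """Moran's I with inverse-squared-Euclidean-distance weights.

        I = (N / W) * sum_ij w_ij (y_i - ybar)(y_j - ybar) / sum_i (y_i - ybar)^2

    with w_ij = 1/d_ij^2, w_ii = 0, W = sum w_ij. With ``truncate_k`` set,
    weights are kept only for each spot's k nearest neighbors and then
    symmetrized. Values near +1 indicate smooth spatial structure; the
    expectation under exchangeability is -1/(N-1).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("need at least 3 spots")
    if n != geom.n_spots:
        raise ValueError("y length does not match geometry")
    z = y - y.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValueError("zero variance: y is constant")
    w = _weight_matrix(geom, truncate_k)
    W = w.sum()
    return float((n / W) * (z @ w @ z) / denom)


def morans_rank(
    mat: ExpressionMatrix, geom: SpotGeometry, truncate_k: int | None = None
) -> list[BaselineRanking]:
    """Rank genes by decreasing Moran's I; constant genes get NaN, ranked last."""
    if mat.layer_tag == "counts":
        raise ValueError("morans_rank expects a transformed layer")
    w = _weight_matrix(geom, truncate_k)
    W = w.sum()
    n = mat.n_spots
    z = mat.values - mat.values.mean(axis=1, keepdims=True)
    denom = np.einsum("gi,gi->g", z, z)
    num = np.einsum("gi,ij,gj->g", z, w, z)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(denom > 0, (n / W) * num / denom, np.nan)
    return _rank_by_score(mat.gene_ids, scores)


def deviance_rank(mat: ExpressionMatrix) -> list[BaselineRanking]:
    """Rank genes by total binomial deviance (sum of squared deviance
    residuals over spots), computed from the counts layer."""
    res = binomial_deviance_residuals(mat)
    scores = np.sum(res.values ** 2, axis=1)
    return _rank_by_score(mat.gene_ids, scores)
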