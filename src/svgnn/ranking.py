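"""Transcriptome-wide driver: fit every gene, test, adjust, rank, combine.

One spatial-model/null-model pair is fitted per gene against a shared
neighbor structure (built once from the geometry and reused, since it does
not depend on the response). Genes are ranked by decreasing LR statistic,
p-values are Benjamini-Hochberg adjusted across all fitted genes, and the
effect size is the proportion of spatial variance propSV = sigma2/(sigma2+tau2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .nngp import (
    NeighborStructure,
    SpotGeometry,
    build_neighbor_structure,
    fit_nngp,
    fit_null_linear,
    lr_test,
)
from .preprocess import ExpressionMatrix

__all__ = [
    "GeneFitResult", "run_svg", "results_to_frame", "significant_svgs",
    "average_ranks", "rank_correlation", "domain_design_matrix",
]

RESULT_COLUMNS = [
    "gene_id", "sigma2", "tau2", "l", "phi", "prop_sv", "loglik_full",
    "loglik_null", "lr_stat", "pval", "padj", "rank", "mean_expr",
]


@dataclass
class GeneFitResult:
    """Per-gene estimates, test statistics and rank (1 = top)."""

    gene_id: str
    sigma2_hat: float
    tau2_hat: float
    l_hat: float
    beta_hat: np.ndarray
    loglik_full: float
    loglik_null: float
    lr_stat: float
    pval: float
    padj: float
    prop_sv: float
    mean_expr: float
    rank: int = 0
    converged: bool = True

    @property
    def phi_hat(self) -> float:
        return 1.0 / self.l_hat if self.l_hat > 0 else np.nan


def domain_design_matrix(domains: np.ndarray | list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept plus one-hot indicators of spatial-domain labels, dropping
    the lexicographically first level as reference."""
    labels = pd.Series([str(d) for d in domains])
    levels = sorted(labels.unique())
    if len(levels) == 1:
        warnings.warn("single domain level; design reduces to intercept-only",
                      stacklevel=2)
        return np.ones((len(labels), 1)), ["intercept"]
    cols = [np.ones(len(labels))]
    names = ["intercept"]
    for lev in levels[1:]:
        cols.append((labels == lev).to_numpy(float))
        names.append(f"domain_{lev}")
    return np.column_stack(cols), names


def run_svg(
    mat: ExpressionMatrix,
    geom: SpotGeometry,
    domains: np.ndarray | list[str] | None = None,
    n_neighbors: int = 10,
    ordering: str = "maxmin",
    ns: NeighborStructure | None = None,
    max_evals: int = 200,
    profile_sigma2: bool = True,
) -> list[GeneFitResult]:
    """Fit the spatial vs nonspatial model pair for every gene and rank.

    ``mat`` must carry a continuous layer (logcounts or deviance residuals).
    If ``domains`` is given, the design matrix is intercept + one-hot domain
    indicators, so spatial variation is tested within domains (domain-wise
    mean shifts are absorbed by the covariates). Constant genes cannot be
    fitted: they get NaN statistics and sort to the bottom.

    Ranks are by decreasing LR; ties broken by higher propSV then gene_id.
    """
    if mat.layer_tag == "counts":
        raise ValueError("run_svg expects a transformed layer "
                         "(logcounts or deviance_residuals)")
    if geom.n_spots != mat.n_spots:
        raise ValueError("geometry does not match expression matrix spot count")
    if domains is not None:
        if len(domains) != mat.n_spots:
            raise ValueError("domain labels do not match spot count")
        X, _ = domain_design_matrix(domains)
    else:
        X = np.ones((mat.n_spots, 1))
    if ns is None:
        ns = build_neighbor_structure(geom, m=n_neighbors, ordering=ordering)

    results: list[GeneFitResult] = []
    for gi, gene in enumerate(mat.gene_ids):
        y = mat.values[gi]
        mean_expr = float(y.mean())
        if np.ptp(y) == 0.0:
            results.append(GeneFitResult(
                gene_id=gene, sigma2_hat=np.nan, tau2_hat=np.nan, l_hat=np.nan,
                beta_hat=np.full(X.shape[1], np.nan), loglik_full=np.nan,
                loglik_null=np.nan, lr_stat=np.nan, pval=np.nan, padj=np.nan,
                prop_sv=np.nan, mean_expr=mean_expr, converged=False,
            ))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = fit_nngp(y, X, ns, max_evals=max_evals,
                            profile_sigma2=profile_sigma2)
        null = fit_null_linear(y, X)
        lr, p = lr_test(full, null)
        s2, t2 = full.params.sigma2, full.params.tau2
        prop_sv = s2 / (s2 + t2) if (s2 + t2) > 0 else np.nan
        results.append(GeneFitResult(
            gene_id=gene, sigma2_hat=s2, tau2_hat=t2,
            l_hat=full.params.length_scale, beta_hat=full.beta,
            loglik_full=full.loglik, loglik_null=null.loglik,
            lr_stat=lr, pval=p, padj=np.nan, prop_sv=prop_sv,
            mean_expr=mean_expr, converged=full.converged,
        ))

    fitted = [r for r in results if np.isfinite(r.pval)]
    if fitted:
        padj = multipletests([r.pval for r in fitted], method="fdr_bh")[1]
        for r, pa in zip(fitted, padj):
            r.padj = float(pa)

    # rank: decreasing LR (NaN last), ties by higher propSV then gene_id
    def sort_key(r: GeneFitResult):
        lr = r.lr_stat if np.isfinite(r.lr_stat) else -np.inf
        ps = r.prop_sv if np.isfinite(r.prop_sv) else -np.inf
        return (-lr, -ps, r.gene_id)

    for rank, r in enumerate(sorted(results, key=sort_key), start=1):
        r.rank = rank
    return results


def results_to_frame(results: list[GeneFitResult]) -> pd.DataFrame:
    """Tabulate results, one row per gene, sorted by rank."""
    rows = [{
        "gene_id": r.gene_id, "sigma2": r.sigma2_hat, "tau2": r.tau2_hat,
        "l": r.l_hat, "phi": r.phi_hat, "prop_sv": r.prop_sv,
        "loglik_full": r.loglik_full, "loglik_null": r.loglik_null,
        "lr_stat": r.lr_stat, "pval": r.pval, "padj": r.padj,
        "rank": r.rank, "mean_expr": r.mean_expr,
    } for r in sorted(results, key=lambda r: r.rank)]
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def significant_svgs(results: list[GeneFitResult], alpha: float = 0.05) -> list[GeneFitResult]:
    """Genes with BH-adjusted p <= alpha, in rank order."""
    keep = [r for r in results if np.isfinite(r.padj) and r.padj <= alpha]
    return sorted(keep, key=lambda r: r.rank)


def average_ranks(per_sample_results: list[list[GeneFitResult]]) -> pd.DataFrame:
    """Combine rankings across samples by averaging within-sample ranks.

    Genes present in every sample are ordered by the arithmetic mean of their
    ranks; genes missing from some samples are placed after all complete
    genes, ordered by the mean of their available ranks. Ties break by
    gene_id. Columns: gene_id, mean_rank, n_samples, combined_rank.
    """
    if len(per_sample_results) < 2:
        raise ValueError("need at least 2 samples to combine")
    rank_maps = [{r.gene_id: r.rank for r in res} for res in per_sample_results]
    all_genes = sorted(set().union(*rank_maps))
    n_total = len(rank_maps)
    rows = []
    for g in all_genes:
        ranks = [m[g] for m in rank_maps if g in m]
        rows.append({"gene_id": g, "mean_rank": float(np.mean(ranks)),
                     "n_samples": len(ranks)})
    shared2 = [r for r in rows if r["n_samples"] >= 2]
    if not shared2:
        raise ValueError("no gene shared by at least 2 samples")
    df = pd.DataFrame(rows)
    df["complete"] = df["n_samples"] == n_total
    df = df.sort_values(
        ["complete", "mean_rank", "gene_id"], ascending=[False, True, True]
    ).reset_index(drop=True)
    df["combined_rank"] = np.arange(1, len(df) + 1)
    return df[["gene_id", "mean_rank", "n_samples", "combined_rank"]]


def rank_correlation(
    results_a: list[GeneFitResult], results_b: list[GeneFitResult]
) -> float:
    """Spearman correlation of within-sample ranks on the shared gene set."""
    ra = {r.gene_id: r.rank for r in results_a}
    rb = {r.gene_id: r.rank for r in results_b}
    shared = sorted(set(ra) & set(rb))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared genes")
    rho = spearmanr([ra[g] for g in shared], [rb[g] for g in shared]).statistic
    return float(rho)
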