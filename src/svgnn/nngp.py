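"""Nearest-neighbor Gaussian process likelihood, ML fitting and the LR test.

The model for one gene's response y at N planar locations is

    y ~ N(X beta, sigma2 * R(l) + tau2 * I),      R_ij = exp(-||s_i - s_j|| / l)

an exponential-kernel GP with a nugget. The exact Gaussian likelihood costs
O(N^3); here it is replaced by a Vecchia factorization of the marginal
covariance in which each location, taken in a max-min ordering, conditions
only on its m nearest previously-ordered neighbors. Every term then requires
one m x m solve, so a likelihood evaluation costs O(N m^3) time and O(N m^2)
memory and the approximation is exact when m >= N - 1.

Fitting maximizes the Vecchia likelihood over the decay phi = 1/l and the
noise ratio alpha = tau2/sigma2 on the log scale, with beta profiled by
generalized least squares and sigma2 profiled analytically (a joint search
including log sigma2 is available). The spatial variance is tested with
LR = 2 (loglik_full - loglik_null) against chi2 with 2 df, the null being the
ordinary linear model with sigma2 = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.stats import chi2

__all__ = [
    "SpotGeometry", "CovarianceParams", "NeighborStructure", "ModelFit",
    "scale_coords", "exp_covariance", "build_neighbor_structure",
    "nngp_loglik", "fit_nngp", "fit_null_linear", "lr_test",
]

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class SpotGeometry:
    """N x 2 spot coordinates scaled so the longer axis spans [0, 1].

    A single scale factor (original units per scaled unit) is applied to both
    axes, preserving the aspect ratio so the isotropic kernel is unaffected
    by the rescaling. Length scales l are expressed in these scaled units.
    """

    coords: np.ndarray
    scale_factor: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be N x 2")
        if self.coords.shape[0] < 2:
            raise ValueError("need at least 2 spots")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords must be finite")

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        return cdist(self.coords, self.coords)


@dataclass
class CovarianceParams:
    """Exponential-kernel parameters: spatial variance sigma2, length scale l
    (scaled-coordinate units) and nugget tau2."""

    sigma2: float
    length_scale: float
    tau2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0 or self.tau2 < 0:
            raise ValueError("variance components must be >= 0")
        if self.sigma2 + self.tau2 <= 0:
            raise ValueError("sigma2 + tau2 must be positive")
        # with no spatial variance the length scale is unidentified (NA ok)
        if self.sigma2 > 0 and not (
            np.isfinite(self.length_scale) and self.length_scale > 0
        ):
            raise ValueError("length_scale must be finite and positive")

    @property
    def phi(self) -> float:
        """Decay rate 1/l."""
        return 1.0 / self.length_scale


def scale_coords(
    raw: np.ndarray,
    jitter: float = 1e-6,
    seed: int | None = 0,
) -> SpotGeometry:
    """Scale raw coordinates into the unit frame.

    Both axes are shifted to start at 0 and divided by the single largest
    axis range, so the longer axis spans [0, 1]. Duplicate locations are
    perturbed by a deterministic tiny jitter (the kernel and the neighbor
    factorization assume distinct sites); pass ``jitter=0`` to reject
    duplicates instead.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[1] != 2:
        raise ValueError("raw coordinates must be N x 2")
    lo = raw.min(axis=0)
    rng_xy = raw.max(axis=0) - lo
    scale = float(rng_xy.max())
    if scale == 0.0:
        raise ValueError("all spots are coincident; cannot scale coordinates")
    coords = (raw - lo) / scale
    # deduplicate
    _, first, counts = np.unique(coords, axis=0, return_index=True, return_counts=True)
    if np.any(counts > 1):
        if jitter <= 0:
            raise ValueError("duplicate spot coordinates")
        warnings.warn(
            "duplicate spot coordinates detected; applying deterministic jitter",
            stacklevel=2,
        )
        dup = np.ones(len(coords), dtype=bool)
        dup[first] = False
        rng = np.random.default_rng(seed)
        coords = coords.copy()
        coords[dup] += rng.uniform(-jitter, jitter, size=(dup.sum(), 2))
    return SpotGeometry(coords, scale_factor=scale)


def exp_covariance(
    geom: SpotGeometry, params: CovarianceParams, i: int, j: int
) -> float:
    """Kernel value sigma2 * exp(-||s_i - s_j|| / l) between two spots.

    The marginal covariance of the response adds tau2 on the diagonal only;
    this function returns the kernel part.
    """
    d = float(np.linalg.norm(geom.coords[i] - geom.coords[j]))
    return params.sigma2 * np.exp(-d / params.length_scale)


def _maxmin_order(coords: np.ndarray) -> np.ndarray:
    """Greedy max-min distance ordering, started at the spot nearest the
    centroid; each subsequent point maximizes its minimum distance to the
    points already ordered. O(N^2), deterministic (ties -> lowest index)."""
    n = coords.shape[0]
    center = coords.mean(axis=0)
    first = int(np.argmin(np.linalg.norm(coords - center, axis=1)))
    order = np.empty(n, dtype=int)
    order[0] = first
    mindist = np.linalg.norm(coords - coords[first], axis=1)
    mindist[first] = -np.inf
    for k in range(1, n):
        nxt = int(np.argmax(mindist))
        order[k] = nxt
        d = np.linalg.norm(coords - coords[nxt], axis=1)
        np.minimum(mindist, d, out=mindist)
        mindist[nxt] = -np.inf
    return order


@dataclass
class NeighborStructure:
    """Ordering permutation plus per-position conditioning sets.

    ``order[k]`` is the original index of the k-th ordered location;
    ``neighbors[k]`` lists the positions (in ordered indexing) of the
    min(k, m) nearest previously-ordered locations. Padded arrays with the
    conditional-factor distance caches are precomputed once and reused for
    every gene and every candidate parameter value.
    """

    order: np.ndarray
    neighbors: list[np.ndarray]
    m: int
    # padded caches (ordered indexing); inf-padding makes padded slots inert
    nbr_idx: np.ndarray = field(repr=False)      # (N, m) int, pad 0
    n_nbrs: np.ndarray = field(repr=False)       # (N,) int
    d_self: np.ndarray = field(repr=False)       # (N, m) distance i -> nbr, pad inf
    d_nbr: np.ndarray = field(repr=False)        # (N, m, m) pairwise among nbrs
    d_max: float = 1.0                           # max pairwise distance

    @property
    def n_spots(self) -> int:
        return len(self.order)


def build_neighbor_structure(
    geom: SpotGeometry, m: int = 10, ordering: str = "maxmin"
) -> NeighborStructure:
    """Order the locations and find each one's nearest previously-ordered
    neighbors.

    ``ordering="maxmin"`` is the default max-min distance ordering, which
    spreads early points across the domain and is what makes small
    conditioning sets informative; ``"coord_sum"`` orders by x + y, a cheap
    fallback. With ``m >= N - 1`` the factorization is exact.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    coords = geom.coords
    n = coords.shape[0]
    if ordering == "maxmin":
        order = _maxmin_order(coords)
    elif ordering == "coord_sum":
        order = np.argsort(coords.sum(axis=1), kind="stable")
    else:
        raise ValueError(f"unknown ordering {ordering!r}")

    oc = coords[order]
    D = cdist(oc, oc)
    m_eff = min(m, n - 1)
    nbr_idx = np.zeros((n, m), dtype=int)
    n_nbrs = np.minimum(np.arange(n), m)
    neighbors: list[np.ndarray] = [np.empty(0, dtype=int)]
    for i in range(1, n):
        k = min(i, m_eff)
        drow = D[i, :i]
        if i <= m_eff:
            nb = np.argsort(drow, kind="stable")
        else:
            part = np.argpartition(drow, k - 1)[:k]
            nb = part[np.argsort(drow[part], kind="stable")]
        neighbors.append(nb.astype(int))
        nbr_idx[i, :k] = nb

    d_self = np.full((n, m), np.inf)
    d_nbr = np.full((n, m, m), np.inf)
    d_nbr[:, np.arange(m), np.arange(m)] = 0.0
    for i in range(1, n):
        k = n_nbrs[i]
        nb = nbr_idx[i, :k]
        d_self[i, :k] = D[i, nb]
        d_nbr[i, :k, :k] = D[np.ix_(nb, nb)]
    return NeighborStructure(
        order=order, neighbors=neighbors, m=m, nbr_idx=nbr_idx,
        n_nbrs=n_nbrs, d_self=d_self, d_nbr=d_nbr, d_max=float(D.max()),
    )


def _vecchia_factors(ns: NeighborStructure, phi: float, alpha: float):
    """Conditional regression weights b and variances f on the correlation
    scale, for correlation matrix K = exp(-phi D) + alpha I.

    Covariance of the response is sigma2 * K. Returns (b, f) with shapes
    (N, m) and (N,); padded neighbor slots contribute weight 0.
    """
    m = ns.m
    K = np.exp(-phi * ns.d_nbr)  # inf-padding -> 0 off-diagonal, 1 diagonal
    K[:, np.arange(m), np.arange(m)] += alpha
    k = np.exp(-phi * ns.d_self)  # pad -> 0
    b = np.linalg.solve(K, k[:, :, None])[:, :, 0]
    f = (1.0 + alpha) - np.einsum("ij,ij->i", b, k)
    if np.any(f <= 0):
        bad = int(np.argmin(f))
        raise FloatingPointError(
            f"non-positive conditional variance at ordered position {bad}; "
            "coordinates may be (near-)duplicated — consider jittering"
        )
    return b, f


def _whiten(ns: NeighborStructure, b: np.ndarray, f: np.ndarray, v: np.ndarray):
    """Apply the Vecchia whitening transform (unit correlation scale) to a
    vector or matrix given in ordered indexing."""
    sf = np.sqrt(f)
    if v.ndim == 1:
        return (v - np.einsum("ij,ij->i", b, v[ns.nbr_idx])) / sf
    return (v - np.einsum("ij,ijk->ik", b, v[ns.nbr_idx])) / sf[:, None]


def nngp_loglik(
    y: np.ndarray,
    X: np.ndarray,
    beta: np.ndarray,
    params: CovarianceParams,
    ns: NeighborStructure,
) -> float:
    """Vecchia log-likelihood of y ~ N(X beta, sigma2 R(l) + tau2 I).

    Exact (equal to the dense Gaussian log density) when ns.m >= N - 1; for
    sigma2 = 0 it reduces to the iid normal log-likelihood with variance tau2
    under any neighbor structure.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    n = y.shape[0]
    if X.shape[0] != n or ns.n_spots != n:
        raise ValueError("dimension mismatch between y, X and neighbor structure")
    r = y - X @ beta
    if params.sigma2 == 0.0:
        return float(-0.5 * (n * (_LOG2PI + np.log(params.tau2)) + (r @ r) / params.tau2))
    alpha = params.tau2 / params.sigma2
    b, f = _vecchia_factors(ns, params.phi, alpha)
    u = _whiten(ns, b, f, r[ns.order])
    s2 = params.sigma2
    return float(-0.5 * (n * (_LOG2PI + np.log(s2)) + np.sum(np.log(f)) + (u @ u) / s2))


@dataclass
class ModelFit:
    """Result of one maximum-likelihood fit."""

    params: CovarianceParams | None
    beta: np.ndarray
    loglik: float
    converged: bool
    n_evals: int = 0


# default initializations: l at {1/4, 1/2, 1} of max scaled distance, alpha 1
_INIT_L_FRACS = (0.25, 0.5, 1.0)
_INIT_ALPHA = 1.0


def fit_nngp(
    y: np.ndarray,
    X: np.ndarray,
    ns: NeighborStructure,
    init: CovarianceParams | None = None,
    max_evals: int = 200,
    rel_tol: float = 1e-6,
    profile_sigma2: bool = True,
) -> ModelFit:
    """Maximum-likelihood fit of the spatial model via the Vecchia likelihood.

    The search is over the unconstrained (log phi, log alpha) with beta
    profiled by generalized least squares and sigma2 profiled analytically
    at each candidate (``profile_sigma2=False`` instead searches jointly over
    (log phi, log alpha, log sigma2)). Bounded quasi-Newton (L-BFGS-B) is
    started from three default initializations (or from ``init`` if given);
    the best optimum is returned. Non-convergence returns the best point
    found with ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if np.ptp(y) == 0.0:
        raise ValueError("y is constant; spatial model is degenerate "
                         "(use fit_null_linear)")
    yo = y[ns.order]
    Xo = X[ns.order]
    d_max = max(ns.d_max, 1e-6)
    n_evals = 0

    def profile_negll(z):
        nonlocal n_evals
        n_evals += 1
        phi, alpha = np.exp(z[0]), np.exp(z[1])
        b, f = _vecchia_factors(ns, phi, alpha)
        yt = _whiten(ns, b, f, yo)
        Xt = _whiten(ns, b, f, Xo)
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        resid = yt - Xt @ beta
        rss = float(resid @ resid)
        if rss <= 0:
            return np.inf
        s2 = rss / n
        return 0.5 * (n * (_LOG2PI + np.log(s2)) + np.sum(np.log(f)) + n)

    def joint_negll(z):
        nonlocal n_evals
        n_evals += 1
        phi, alpha, s2 = np.exp(z[0]), np.exp(z[1]), np.exp(z[2])
        b, f = _vecchia_factors(ns, phi, alpha)
        yt = _whiten(ns, b, f, yo)
        Xt = _whiten(ns, b, f, Xo)
        beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
        resid = yt - Xt @ beta
        rss = float(resid @ resid)
        return 0.5 * (n * (_LOG2PI + np.log(s2)) + np.sum(np.log(f)) + rss / s2)

    if init is not None:
        alpha0 = init.tau2 / init.sigma2 if init.sigma2 > 0 else _INIT_ALPHA
        starts = [(np.log(init.phi), np.log(max(alpha0, 1e-8)))]
    else:
        starts = [
            (np.log(1.0 / (frac * d_max)), np.log(_INIT_ALPHA))
            for frac in _INIT_L_FRACS
        ]

    # phi in [1/(10 d_max), 500/d_max]; alpha in [1e-6, 1e6]
    bounds2 = [
        (np.log(1.0 / (10.0 * d_max)), np.log(500.0 / d_max)),
        (np.log(1e-6), np.log(1e6)),
    ]
    lo = np.array([b[0] for b in bounds2])
    hi = np.array([b[1] for b in bounds2])
    starts = [np.clip(np.asarray(z0), lo, hi) for z0 in starts]
    best = None
    converged = False
    for z0 in starts:
        if profile_sigma2:
            res = minimize(
                profile_negll, np.asarray(z0), method="L-BFGS-B", bounds=bounds2,
                options={"maxfun": max_evals, "ftol": rel_tol},
            )
        else:
            var_y = float(np.var(y))
            z0j = np.append(z0, np.log(var_y / 2.0))
            res = minimize(
                joint_negll, z0j, method="L-BFGS-B",
                bounds=bounds2 + [(np.log(var_y * 1e-8), np.log(var_y * 1e4))],
                options={"maxfun": max_evals, "ftol": rel_tol},
            )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    z = best.x
    phi, alpha = np.exp(z[0]), np.exp(z[1])
    b, f = _vecchia_factors(ns, phi, alpha)
    yt = _whiten(ns, b, f, yo)
    Xt = _whiten(ns, b, f, Xo)
    beta, *_ = np.linalg.lstsq(Xt, yt, rcond=None)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    if profile_sigma2:
        s2 = rss / n
    else:
        s2 = float(np.exp(z[2]))
    loglik = -0.5 * (n * (_LOG2PI + np.log(s2)) + np.sum(np.log(f)) + rss / s2)
    if not converged:
        warnings.warn("optimizer did not report convergence; returning best "
                      "parameters found", stacklevel=2)
    params = CovarianceParams(sigma2=s2, length_scale=1.0 / phi, tau2=alpha * s2)
    return ModelFit(params=params, beta=np.asarray(beta), loglik=float(loglik),
                    converged=converged, n_evals=n_evals)


def fit_null_linear(y: np.ndarray, X: np.ndarray) -> ModelFit:
    """ML fit of the nonspatial linear model y ~ N(X beta, tau2 I).

    beta is OLS and tau2 = RSS / N (the ML, not REML, variance). This is the
    sigma2 = 0 null of the LR test.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, d = X.shape
    if d > n:
        raise ValueError("more covariates than observations")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    if rss <= 1e-12 * max(1.0, float(y @ y)):
        raise ValueError("residuals are (near) zero; variance estimate degenerate")
    tau2 = rss / n
    loglik = -0.5 * n * (_LOG2PI + np.log(tau2) + 1.0)
    params = CovarianceParams(sigma2=0.0, length_scale=np.nan, tau2=tau2)
    return ModelFit(params=params, beta=np.asarray(beta), loglik=float(loglik),
                    converged=True, n_evals=1)


def lr_test(full: ModelFit, null: ModelFit) -> tuple[float, float]:
    """Likelihood-ratio test of sigma2 = 0.

    LR = 2 (loglik_full - loglik_null); p is the upper chi2(2 df) tail at
    max(LR, 0). Small negative LR values (the approximate likelihood is not
    strictly nested) are reported as-is, with p computed at 0, i.e. p = 1.
    """
    lr = 2.0 * (full.loglik - null.loglik)
    p = float(chi2.sf(max(lr, 0.0), df=2))
    return float(lr), p
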