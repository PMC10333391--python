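"""NNGP likelihood core: geometry scaling, neighbor structure, the Vecchia
likelihood against the dense-Gaussian oracle, ML fitting and the LR test."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.stats import multivariate_normal

from svgnn import (
    CovarianceParams,
    SpotGeometry,
    build_neighbor_structure,
    exp_covariance,
    fit_nngp,
    fit_null_linear,
    lr_test,
    nngp_loglik,
    scale_coords,
)
from conftest import draw_gp_data


def dense_loglik(y, X, beta, params, coords):
    """Independent oracle: exact dense multivariate-normal log density."""
    D = cdist(coords, coords)
    cov = params.sigma2 * np.exp(-D / params.length_scale) \
        + params.tau2 * np.eye(len(y))
    return multivariate_normal.logpdf(y, mean=X @ beta, cov=cov)


class TestScaleCoords:
    def test_longer_axis_spans_unit_and_aspect_preserved(self):
        raw = np.array([[0, 0], [100, 50], [50, 25], [0, 50]])
        geom = scale_coords(raw)
        assert geom.scale_factor == 100
        assert geom.coords[:, 0].max() == pytest.approx(1.0)
        assert geom.coords[:, 1].max() == pytest.approx(0.5)

    def test_unit_square_is_identity(self):
        raw = np.array([[0.0, 0.0], [1.0, 1.0], [0.3, 0.7]])
        geom = scale_coords(raw)
        np.testing.assert_allclose(geom.coords, raw)
        assert geom.scale_factor == 1.0

    def test_translation_leaves_pairwise_distances_unchanged(self, rng):
        raw = rng.random((20, 2)) * 7.0
        d0 = cdist(*(2 * [scale_coords(raw).coords]))
        d1 = cdist(*(2 * [scale_coords(raw + np.array([13.0, -4.0])).coords]))
        np.testing.assert_allclose(d0, d1, atol=1e-12)

    def test_coincident_spots_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            scale_coords(np.array([[1.0, 2.0], [1.0, 2.0]]))

    def test_duplicates_jittered_with_warning(self):
        raw = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="jitter"):
            geom = scale_coords(raw)
        assert len(np.unique(geom.coords, axis=0)) == 3


class TestExpCovariance:
    def test_zero_distance_gives_sigma2(self, small_geom):
        p = CovarianceParams(2.0, 0.3, 0.7)
        assert exp_covariance(small_geom, p, 3, 3) == pytest.approx(2.0)

    def test_unit_argument_decay(self):
        geom = SpotGeometry(np.array([[0.0, 0.0], [0.3, 0.0]]))
        p = CovarianceParams(1.5, 0.3, 0.0)
        assert exp_covariance(geom, p, 0, 1) == pytest.approx(1.5 * np.exp(-1))

    def test_monotone_decay_with_distance(self):
        geom = SpotGeometry(np.array([[0, 0], [0.1, 0], [0.5, 0], [3.0, 0.0]]))
        p = CovarianceParams(1.0, 0.2, 0.0)
        vals = [exp_covariance(geom, p, 0, j) for j in range(1, 4)]
        assert vals[0] > vals[1] > vals[2] > 0


class TestNeighborStructure:
    def test_first_position_has_no_neighbors(self, small_geom):
        ns = build_neighbor_structure(small_geom, m=5)
        assert ns.neighbors[0].size == 0

    def test_neighbor_counts_saturate(self, small_geom):
        n = small_geom.n_spots
        ns = build_neighbor_structure(small_geom, m=n + 5)
        for i in range(n):
            assert len(ns.neighbors[i]) == min(i, n - 1)

    def test_neighbors_precede_and_are_nearest(self, small_geom):
        ns = build_neighbor_structure(small_geom, m=4)
        oc = small_geom.coords[ns.order]
        D = cdist(oc, oc)
        for i in range(1, small_geom.n_spots):
            nb = ns.neighbors[i]
            assert np.all(nb < i)
            k = min(i, 4)
            best = np.sort(np.argsort(D[i, :i], kind="stable")[:k])
            assert set(nb) == set(best)

    def test_collinear_coord_sum_neighbors_are_immediate_predecessors(self):
        geom = SpotGeometry(np.array([[i, 0.0] for i in range(5)], dtype=float))
        ns = build_neighbor_structure(geom, m=2, ordering="coord_sum")
        np.testing.assert_array_equal(ns.order, np.arange(5))
        for k in range(2, 5):
            assert set(ns.neighbors[k]) == {k - 1, k - 2}

    def test_maxmin_starts_near_centroid_and_spreads(self):
        side = 7
        xs, ys = np.meshgrid(np.arange(side), np.arange(side))
        geom = SpotGeometry(np.column_stack([xs.ravel(), ys.ravel()]) / (side - 1))
        ns = build_neighbor_structure(geom, m=3)
        center = geom.coords.mean(axis=0)
        d_first = np.linalg.norm(geom.coords[ns.order[0]] - center)
        assert d_first == np.min(np.linalg.norm(geom.coords - center, axis=1))
        # the second ordered point maximizes distance from the first
        d = np.linalg.norm(geom.coords - geom.coords[ns.order[0]], axis=1)
        assert d[ns.order[1]] == pytest.approx(d.max())


class TestVecchiaLoglik:
    def test_exact_when_m_saturates(self, rng):
        """With m = n - 1 the factorization equals the dense log density."""
        for _ in range(20):
            n = int(rng.integers(5, 40))
            coords = rng.random((n, 2))
            geom = SpotGeometry(coords)
            ns = build_neighbor_structure(geom, m=n - 1)
            y = rng.standard_normal(n)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            beta = rng.standard_normal(2)
            p = CovarianceParams(
                float(rng.uniform(0.1, 3.0)), float(rng.uniform(0.05, 1.0)),
                float(rng.uniform(0.01, 2.0)),
            )
            got = nngp_loglik(y, X, beta, p, ns)
            want = dense_loglik(y, X, beta, p, coords)
            assert got == pytest.approx(want, abs=1e-8)

    def test_sigma2_zero_reduces_to_iid_normal(self, rng, small_geom):
        n = small_geom.n_spots
        ns = build_neighbor_structure(small_geom, m=6)
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        beta = np.array([0.2])
        p = CovarianceParams(0.0, 1.0, 0.8)
        r = y - 0.2
        want = -0.5 * np.sum(np.log(2 * np.pi * 0.8) + r ** 2 / 0.8)
        assert nngp_loglik(y, X, beta, p, ns) == pytest.approx(want)

    def test_approximation_error_small_at_m_10(self, rng):
        n = 40
        coords = rng.random((n, 2))
        geom = SpotGeometry(coords)
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        beta = np.array([0.0])
        p = CovarianceParams(1.0, 0.2, 0.5)
        dense = dense_loglik(y, X, beta, p, coords)
        ns10 = build_neighbor_structure(geom, m=10)
        got = nngp_loglik(y, X, beta, p, ns10)
        assert abs((got - dense) / dense) <= 1e-2

    def test_rigid_motion_invariance(self, rng):
        """Translation + rotation of the coordinates leaves the likelihood
        unchanged (isotropic kernel)."""
        n = 30
        coords = rng.random((n, 2))
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        moved = coords @ R.T + np.array([5.0, -2.0])
        y = rng.standard_normal(n)
        X = np.ones((n, 1))
        beta = np.array([0.1])
        p = CovarianceParams(1.3, 0.25, 0.4)
        ll0 = nngp_loglik(y, X, beta, p,
                          build_neighbor_structure(SpotGeometry(coords), m=8))
        ll1 = nngp_loglik(y, X, beta, p,
                          build_neighbor_structure(SpotGeometry(moved), m=8))
        assert ll0 == pytest.approx(ll1, rel=1e-9)


class TestFitNNGP:
    def test_fitted_loglik_beats_initial_params(self, rng):
        coords, y = draw_gp_data(rng, 150, 1.0, 0.2, 0.5)
        geom = SpotGeometry(coords)
        ns = build_neighbor_structure(geom, m=10)
        X = np.ones((150, 1))
        init = CovarianceParams(1.0, 0.5, 1.0)
        fit = fit_nngp(y, X, ns, init=init)
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        ll_init = nngp_loglik(y, X, beta0, init, ns)
        assert fit.loglik >= ll_init - 1e-6

    def test_profiled_and_joint_sigma2_agree(self, rng):
        coords, y = draw_gp_data(rng, 120, 1.0, 0.2, 0.5)
        ns = build_neighbor_structure(SpotGeometry(coords), m=10)
        X = np.ones((120, 1))
        f1 = fit_nngp(y, X, ns, profile_sigma2=True)
        f2 = fit_nngp(y, X, ns, profile_sigma2=False)
        assert f1.loglik == pytest.approx(f2.loglik, abs=0.1)

    def test_constant_y_rejected(self, small_geom):
        ns = build_neighbor_structure(small_geom, m=5)
        with pytest.raises(ValueError, match="constant"):
            fit_nngp(np.ones(small_geom.n_spots),
                     np.ones((small_geom.n_spots, 1)), ns)


class TestFitNullLinear:
    def test_intercept_only_closed_form(self, rng):
        y = rng.standard_normal(50) * 2.0 + 1.0
        X = np.ones((50, 1))
        fit = fit_null_linear(y, X)
        v = np.mean((y - y.mean()) ** 2)
        want = -50 / 2 * (np.log(2 * np.pi * v) + 1)
        assert fit.loglik == pytest.approx(want)
        assert fit.params.tau2 == pytest.approx(v)
        assert fit.beta[0] == pytest.approx(y.mean())

    def test_matches_nngp_loglik_at_sigma2_zero(self, rng, small_geom):
        """Cross-check between the two likelihood code paths."""
        n = small_geom.n_spots
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        fit = fit_null_linear(y, X)
        ns = build_neighbor_structure(small_geom, m=5)
        p = CovarianceParams(0.0, 1.0, fit.params.tau2)
        assert fit.loglik == pytest.approx(nngp_loglik(y, X, fit.beta, p, ns))

    def test_zero_residuals_degenerate(self):
        X = np.ones((5, 1))
        with pytest.raises(ValueError, match="zero"):
            fit_null_linear(np.full(5, 3.0), X)

    def test_overparameterized_design_rejected(self, rng):
        with pytest.raises(ValueError, match="covariates"):
            fit_null_linear(rng.standard_normal(3), rng.standard_normal((3, 5)))


class TestLRTest:
    def test_equal_logliks_give_lr_zero_p_one(self):
        from svgnn.nngp import ModelFit
        a = ModelFit(None, np.zeros(1), -10.0, True)
        b = ModelFit(None, np.zeros(1), -10.0, True)
        assert lr_test(a, b) == (0.0, 1.0)

    @pytest.mark.parametrize("lr,p", [(5.991, 0.05), (13.816, 0.001)])
    def test_chi2_two_df_quantiles(self, lr, p):
        from svgnn.nngp import ModelFit
        full = ModelFit(None, np.zeros(1), lr / 2.0, True)
        null = ModelFit(None, np.zeros(1), 0.0, True)
        got_lr, got_p = lr_test(full, null)
        assert got_lr == pytest.approx(lr)
        assert got_p == pytest.approx(p, rel=5e-3)

    def test_negative_lr_preserved_with_p_one(self):
        from svgnn.nngp import ModelFit
        full = ModelFit(None, np.zeros(1), -10.001, True)
        null = ModelFit(None, np.zeros(1), -10.0, True)
        got_lr, got_p = lr_test(full, null)
        assert got_lr == pytest.approx(-0.002)
        assert got_p == 1.0
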