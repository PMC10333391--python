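"""Shared fixtures.

The heavier simulation-study fixtures are session-scoped so that several
tests can reuse one transcriptome-wide pipeline run.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from svgnn import (
    ExpressionMatrix,
    SimScenario,
    SpotGeometry,
    generate,
    run_svg,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geom(rng):
    """40 random planar locations in the unit square."""
    return SpotGeometry(rng.random((40, 2)))


@pytest.fixture
def toy_counts():
    """4 genes x 6 spots with known structure, including a mitochondrial gene."""
    counts = np.array([
        [5, 0, 2, 8, 1, 0],
        [0, 0, 0, 1, 0, 0],
        [3, 3, 3, 3, 3, 3],
        [10, 20, 5, 0, 7, 2],
    ])
    return ExpressionMatrix(
        counts,
        gene_ids=["GENE_A", "GENE_B", "GENE_C", "MT-CO1"],
        spot_ids=[f"s{i}" for i in range(6)],
    )


def draw_gp_data(rng, n, sigma2, length_scale, tau2, beta0=0.0):
    """Draw (coords, y) exactly from the exponential-GP-plus-nugget model,
    via the dense Cholesky factor. Used as generative truth in recovery and
    calibration tests."""
    coords = rng.random((n, 2))
    D = cdist(coords, coords)
    cov = sigma2 * np.exp(-D / length_scale) + tau2 * np.eye(n)
    y = beta0 + np.linalg.cholesky(cov) @ rng.standard_normal(n)
    return coords, y


# ---------------------------------------------------------------------------
# simulation-study fixtures (shared by the acceptance suite)
# ---------------------------------------------------------------------------

MEDIUM_SCENARIO = dict(
    n_spots=1000, radius_frac=0.125, strength_frac=1.0 / 3.0,
    n_svg=20, n_noise=200, seed=11,
)


@pytest.fixture(scope="session")
def medium_dataset():
    """Medium-radius / medium-strength hotspot scenario, 220 genes, 1000 spots."""
    return generate(SimScenario(**MEDIUM_SCENARIO))


@pytest.fixture(scope="session")
def medium_results(medium_dataset):
    """Full per-gene LR pipeline on the medium scenario."""
    ds = medium_dataset
    return run_svg(ds.mat, ds.geom)
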