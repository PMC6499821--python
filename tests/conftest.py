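import numpy as np
import pytest

from langdiv.gls import CorrelationParams, build_correlation
from langdiv.grid import GridSpec
from langdiv.synthetic import SynthConfig, design_matrix, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


def small_config(seed, n_rows=5, n_cols=5, cell_km=400.0, *, alpha=0.7,
                 beta=0.5, gamma=800.0, sigma2=0.3, **overrides):
    """Desk-scale synthetic config: an occupied planar grid of <= n_rows*n_cols
    cells with a single continuous predictor."""
    defaults = dict(
        seed=seed,
        grid=GridSpec(
            mode="planar",
            cell_size_km=cell_km,
            extent=(0.0, 0.0, n_cols * cell_km, n_rows * cell_km),
        ),
        n_families=6,
        mean_languages_per_family=5.0,
        homeland_dispersion_km=cell_km,
        family_dispersion_log_sd=0.0,
        true_params=CorrelationParams(alpha, beta, gamma),
        sigma2=sigma2,
        predictors=("annual_mean_temperature",),
        coefficients=(1.0, 0.5),
    )
    defaults.update(overrides)
    return SynthConfig(**defaults)


def gls_instance(seed, n_cells=None, config=None):
    """(y, X, names, P, d, truth) from a fresh synthetic draw, optionally
    truncated to the first n_cells occupied cells."""
    from langdiv.similarity import pairwise_distances, phylosor_matrix
    from langdiv.synthetic import gen_response, _streams

    config = config or small_config(seed)
    data = simulate_dataset(config)
    cells = data.cells
    if n_cells is not None and len(cells) > n_cells:
        cells = cells.iloc[:n_cells].reset_index(drop=True)
        P = phylosor_matrix(data.tree, cells)
        d = pairwise_distances(cells)
        X, names = design_matrix(cells, config.predictors)
        y = gen_response(config, X, P, d, _streams(config.seed, 3)[2])
    else:
        P, d, X, names, y = data.P, data.d, data.X, data.names, data.y
    return y, X, names, P, d, config


@pytest.fixture(scope="session")
def medium_dataset():
    """One moderately sized simulated dataset shared across read-only tests."""
    return simulate_dataset(SynthConfig(seed=7))


def correlated_design(seed, n_side=12, cell_km=300.0, params=None, sigma2=0.3):
    """Fixed occupancy plus a function drawing (x, y) pairs under the null.

    The predictor is drawn from N(0, C) with the same spatial+phylogenetic
    correlation as the model errors, its true coefficient is zero, so any
    drop-one rejection is a type-I error.
    """
    params = params or CorrelationParams(0.8, 0.5, 2.0 * cell_km)
    cfg = small_config(seed, n_rows=n_side, n_cols=n_side, cell_km=cell_km,
                       alpha=params.alpha, beta=params.beta,
                       gamma=params.gamma_km, sigma2=sigma2,
                       n_families=12, mean_languages_per_family=6.0)
    data = simulate_dataset(cfg)
    C = build_correlation(params, data.P, data.d)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(C)))
    n = len(C)

    def draw(rng):
        x = L @ rng.standard_normal(n)
        eps = np.sqrt(sigma2) * (L @ rng.standard_normal(n))
        y = 1.0 + 0.0 * x + eps
        X = np.column_stack([np.ones(n), x])
        return y, X

    return data.P, data.d, draw, n
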