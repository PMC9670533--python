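"""Buffered extraction, fractional polynomials, pruning and elimination."""

import numpy as np
import pandas as pd
import pytest

from geocci.covariates import (
    CovariateMatrix,
    backward_eliminate,
    buffer_extract,
    build_covariate_matrix,
    fractional_polynomial_candidates,
    prune_collinear,
    select_best_fp,
    select_covariates,
)
from geocci.grid import RasterGrid


# ---------------------------------------------------------------------------
# buffer extraction
# ---------------------------------------------------------------------------

def _km1_grid(values):
    return RasterGrid(np.asarray(values, float), 0.0, 0.0, 1.0)


def test_constant_raster_any_buffer():
    g = _km1_grid(np.full((20, 20), 3.25))
    for urban in (True, False):
        assert buffer_extract(g, (10.3, 7.9), urban) == pytest.approx(3.25)


def test_urban_disc_mean_matches_enumeration():
    """1 km cells, urban point at a cell center: the mean runs over exactly
    the 13 cells whose centers lie within 2 km."""
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 10, (21, 21))
    g = _km1_grid(vals)
    pt = (10.5, 10.5)  # a cell center
    centers = g.cell_centers()
    d = np.hypot(centers[:, 0] - pt[0], centers[:, 1] - pt[1])
    inside = d <= 2.0
    assert inside.sum() == 13
    expected = vals.ravel()[inside].mean()
    assert buffer_extract(g, pt, urban=True) == pytest.approx(expected, rel=1e-12)


def test_rural_buffer_widens_along_gradient():
    """On a gradient raster the 5 km rural disc mean differs from the urban
    one in the gradient direction; both equal brute-force disc means."""
    xs = np.arange(30) + 0.5
    vals = np.tile(xs, (30, 1))  # value increases with x
    g = _km1_grid(vals)
    pt = (10.2, 15.0)
    centers = g.cell_centers()
    d = np.hypot(centers[:, 0] - pt[0], centers[:, 1] - pt[1])
    urban_mean = vals.ravel()[d <= 2.0].mean()
    rural_mean = vals.ravel()[d <= 5.0].mean()
    assert buffer_extract(g, pt, urban=True) == pytest.approx(urban_mean, rel=1e-12)
    assert buffer_extract(g, pt, urban=False) == pytest.approx(rural_mean, rel=1e-12)
    assert buffer_extract(g, pt, True) != buffer_extract(g, pt, False)


def test_coarse_cells_fall_back_to_containing_cell():
    g = RasterGrid(np.arange(16, dtype=float).reshape(4, 4), 0.0, 0.0, 10.0)
    # 2 km urban buffer around a point far from any 10 km cell center
    assert buffer_extract(g, (1.0, 39.0), urban=True) == g.value_at(1.0, 39.0)


def test_zero_radius_buffer_is_nearest_cell_lookup():
    rng = np.random.default_rng(4)
    g = _km1_grid(rng.uniform(0, 1, (10, 10)))
    pt = (3.3, 6.1)
    v = buffer_extract(g, pt, urban=True, urban_radius=1e-9, rural_radius=1e-9)
    assert v == g.value_at(*pt)


def test_nodata_excluded_from_buffer():
    vals = np.full((21, 21), 2.0)
    vals[10, 10] = np.nan  # center cell is nodata
    g = _km1_grid(vals)
    assert buffer_extract(g, (10.5, 10.5), urban=True) == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# fractional polynomials
# ---------------------------------------------------------------------------

def test_fp_candidate_closed_forms():
    x = np.array([1.0, np.e, np.e**2])
    cands = dict(
        (powers, cols) for powers, cols in fractional_polynomial_candidates(x)
    )
    assert np.allclose(cands[(0.0,)].ravel(), [0, 1, 2])
    assert np.allclose(cands[(1.0,)].ravel(), x)
    x2 = np.array([1.0, 4.0])
    cands2 = dict(
        (powers, cols) for powers, cols in fractional_polynomial_candidates(x2)
    )
    pair = cands2[(0.5, 0.5)]
    # repeated power (p, p) -> (x^p, x^p ln x); at x = 4: (2, 2*ln 4)
    assert np.allclose(pair[:, 0], [1.0, 2.0])
    assert np.allclose(pair[:, 1], [0.0, 2.0 * np.log(4.0)])


def test_fp_candidate_counts_and_domain():
    x = np.linspace(1, 5, 20)
    cands = fractional_polynomial_candidates(x)
    assert len(cands) == 8 + 36
    with pytest.raises(ValueError, match="positive"):
        fractional_polynomial_candidates(np.array([0.0, 1.0]))


def test_select_best_fp_recovers_generative_transforms():
    """Log-generated outcomes select the log; linear ones stay linear."""
    rng = np.random.default_rng(42)
    n = 2000
    x = rng.uniform(0.5, 8.0, n)
    trials = rng.poisson(5, n) + 1
    from scipy.special import expit

    y_log = rng.binomial(trials, expit(-1.2 + 1.5 * np.log(x)))
    res = select_best_fp(y_log, trials, x)
    assert 0.0 in res.powers
    assert not res.weak

    y_lin = rng.binomial(trials, expit(-1.0 + 0.6 * x))
    res_lin = select_best_fp(y_lin, trials, x)
    assert res_lin.powers == (1.0,)

    # independent covariate: flagged weak, left linear
    y_null = rng.binomial(trials, 0.4)
    res_null = select_best_fp(y_null, trials, x)
    assert res_null.weak
    assert res_null.powers == (1.0,)


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _matrix(cols: dict) -> CovariateMatrix:
    df = pd.DataFrame(cols)
    return CovariateMatrix(np.array([f"C{i}" for i in range(len(df))]), df)


def test_prune_identical_columns_keeps_one():
    rng = np.random.default_rng(1)
    a = rng.standard_normal(100)
    m = _matrix({"a": a, "b": a.copy()})
    pruned, log = prune_collinear(m, {"a": 2.0, "b": 1.0})
    assert pruned.columns == ["a"]
    assert log[0][0] == "b"


def test_prune_correlated_trio_keeps_top_scorer():
    rng = np.random.default_rng(2)
    base = rng.standard_normal(500)
    cols = {
        "a": base + 0.1 * rng.standard_normal(500),
        "b": base + 0.1 * rng.standard_normal(500),
        "c": base + 0.1 * rng.standard_normal(500),
    }
    m = _matrix(cols)
    scores = {"a": 1.0, "b": 3.0, "c": 2.0}
    pruned, _ = prune_collinear(m, scores)
    assert pruned.columns == ["b"]
    corr = pruned.data.corr().abs().to_numpy()
    assert np.all(corr[~np.eye(len(corr), dtype=bool)] <= 0.8)


def test_prune_noop_below_threshold():
    rng = np.random.default_rng(3)
    m = _matrix({"a": rng.standard_normal(300), "b": rng.standard_normal(300)})
    pruned, log = prune_collinear(m, {"a": 1.0, "b": 2.0})
    assert pruned.columns == ["a", "b"]
    assert log == []


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

def _sim_outcome(rng, X, beta, n=None, mean_trials=5):
    from scipy.special import expit

    trials = rng.poisson(mean_trials, len(X)) + 1
    y = rng.binomial(trials, expit(X @ np.asarray(beta)))
    return y, trials


def test_backward_elimination_keeps_signal_drops_noise():
    """Over replicates, the generative covariate survives and pure noise is
    dropped first in the overwhelming majority of runs."""
    rng = np.random.default_rng(7)
    kept_signal = 0
    noise_first = 0
    reps = 25
    for _ in range(reps):
        n = 800
        sig = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        y, trials = _sim_outcome(rng, np.column_stack([np.ones(n), sig]), [0.2, 0.8])
        m = _matrix({"signal": sig, "noise": noise})
        final, trace, pvals = backward_eliminate(y, trials, m)
        if "signal" in final.columns:
            kept_signal += 1
        if trace and trace[0][0] == "noise":
            noise_first += 1
        # elimination trace: each drop had the max p at its step, above 0.05
        for _, p in trace:
            assert p > 0.05
    assert kept_signal >= int(0.9 * reps)
    assert noise_first >= int(0.9 * reps)


def test_backward_elimination_keeps_all_strong_covariates():
    rng = np.random.default_rng(8)
    n = 2000
    x1, x2, x3 = (rng.standard_normal(n) for _ in range(3))
    y, trials = _sim_outcome(
        rng, np.column_stack([np.ones(n), x1, x2, x3]), [0.0, 0.6, -0.5, 0.4]
    )
    final, trace, pvals = backward_eliminate(y, trials, _matrix({"x1": x1, "x2": x2, "x3": x3}))
    assert final.columns == ["x1", "x2", "x3"]
    assert trace == []
    assert all(p <= 0.05 for p in pvals.values())


def test_full_selection_pipeline_on_survey(small_grid):
    """End-to-end selection on a synthetic survey returns a report whose
    final covariates all pass the 5% Wald threshold."""
    from geocci.synthetic import SyntheticConfig, generate

    cfg = SyntheticConfig(
        seed=12, region_size_km=100.0, cell_km=5.0, n_admin1=2,
        n_admin2_per_admin1=2, n_clusters=500,
    )
    b = generate(cfg)
    matrix, report = select_covariates(
        b.dataset, "DPT3", rasters=b.field.covariates
    )
    assert set(report.final_covariates) == set(matrix.columns)
    assert all(p <= 0.05 for p in report.final_pvalues.values())
    # the matrix covers every cluster, aligned
    assert len(matrix.cluster_ids) == b.dataset.n_clusters
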