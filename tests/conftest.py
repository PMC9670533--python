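"""Shared fixtures: small grids and directly simulated GP-binomial surveys.

The heavier end-to-end artifacts (the demo pipeline run) are session-scoped
so several tests can interrogate one run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist
from scipy.special import expit

from geocci.grid import RasterGrid
from geocci.model import _matern_corr_matrix
from geocci.survey import SurveyDataset


@pytest.fixture
def small_grid() -> RasterGrid:
    return RasterGrid(np.zeros((10, 10)), 0.0, 0.0, 5.0)


def simulate_gp_survey(
    n: int,
    beta: np.ndarray,
    sigma_omega: float = 0.7,
    range_rho: float = 25.0,
    sigma_eps: float = 0.3,
    region: float = 100.0,
    mean_trials: float = 5.0,
    indicator: str = "DPT3",
    seed: int = 0,
    presence: float = 1.0,
):
    """Single-indicator survey drawn exactly from the model's data process.

    Returns (dataset, X, coords, p_true) where p_true is the nugget-free
    probability at the cluster locations.
    """
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, region, (n, 2))
    p_cov = len(beta) - 1
    X = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(p_cov)])
    C = sigma_omega**2 * _matern_corr_matrix(cdist(coords, coords), range_rho, 1.0)
    omega = np.linalg.cholesky(C + 1e-8 * sigma_omega**2 * np.eye(n)) @ rng.standard_normal(n)
    eta_free = X @ np.asarray(beta) + omega
    p_true = expit(eta_free)
    eps = rng.normal(0, sigma_eps, n) if sigma_eps > 0 else 0.0
    trials = rng.poisson(mean_trials - 1, n) + 1
    if presence < 1.0:
        trials = np.where(rng.uniform(size=n) < presence, trials, 0)
    y = rng.binomial(trials, expit(eta_free + eps))
    table = pd.DataFrame(
        {
            "cluster_id": [f"C{i:04d}" for i in range(n)],
            "x": coords[:, 0],
            "y": coords[:, 1],
            "urban": False,
            "round": 2018,
            "indicator": indicator,
            "events": y,
            "trials": trials,
        }
    )
    return SurveyDataset(table), X, coords, p_true


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full desk-scale pipeline run (grid 40×40, 300 clusters, S=200)."""
    from geocci.pipeline import demo_config, run_pipeline

    out = tmp_path_factory.mktemp("demo")
    cfg = demo_config(str(out), seed=20240)
    manifest, results = run_pipeline(cfg)
    return cfg, manifest, results
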