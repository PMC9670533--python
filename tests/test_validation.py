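"""Fold construction, CV metrics and the modelled-vs-direct comparison."""

import numpy as np
import pandas as pd
import pytest

from geocci.admin import AdminHierarchy
from geocci.survey import SurveyDataset
from geocci.validation import (
    compare_admin,
    cross_validate,
    direct_admin_estimate,
    make_folds,
    prediction_metrics,
)
from geocci.model import ModelSpec

from conftest import simulate_gp_survey


def _single_indicator_dataset(n_eligible, n_total=None, indicator="ORS", seed=0):
    rng = np.random.default_rng(seed)
    n_total = n_total or n_eligible
    trials = np.zeros(n_total, dtype=int)
    trials[:n_eligible] = rng.poisson(3, n_eligible) + 1
    table = pd.DataFrame(
        {
            "cluster_id": [f"C{i:05d}" for i in range(n_total)],
            "x": rng.uniform(0, 100, n_total),
            "y": rng.uniform(0, 100, n_total),
            "urban": False,
            "round": 2018,
            "indicator": indicator,
            "events": rng.binomial(trials, 0.5),
            "trials": trials,
        }
    )
    return SurveyDataset(table)


def test_folds_exact_at_the_floor():
    ds = _single_indicator_dataset(250)
    folds = make_folds(ds, "ORS", K=5, seed=1)
    assert sorted(folds.eligible_per_fold.values()) == [50] * 5
    # partition: disjoint and exhaustive
    assert len(folds.assignment) == 250
    assert set(folds.assignment.values()) == {1, 2, 3, 4, 5}


def test_folds_balanced_for_large_n():
    ds = _single_indicator_dataset(3301)
    folds = make_folds(ds, "ORS", K=5, seed=2)
    sizes = sorted(folds.eligible_per_fold.values())
    assert all(s >= 50 for s in sizes)
    assert max(sizes) - min(sizes) <= 1
    assert sum(sizes) == 3301


def test_folds_infeasible_raises_with_deficit():
    ds = _single_indicator_dataset(180)
    with pytest.raises(ValueError, match="deficit"):
        make_folds(ds, "ORS", K=5)


def test_single_fold_degenerate():
    ds = _single_indicator_dataset(60)
    folds = make_folds(ds, "ORS", K=1, seed=0)
    assert set(folds.assignment.values()) == {1}


def test_metrics_hand_example():
    me, mae, r = prediction_metrics([0.2, 0.4, 0.6], [0.3, 0.4, 0.5])
    assert me == pytest.approx(0.0, abs=1e-15)
    assert mae == pytest.approx(2.0 / 30.0, rel=1e-12)
    assert r == pytest.approx(1.0, abs=1e-12)


def test_metrics_perfect_prediction():
    obs = np.array([0.1, 0.5, 0.9, 0.4])
    me, mae, r = prediction_metrics(obs, obs)
    assert (me, mae, r) == (0.0, 0.0, 1.0)


def test_metrics_order_invariant_and_triangle_bound():
    rng = np.random.default_rng(5)
    pred = rng.uniform(0, 1, 100)
    obs = rng.uniform(0, 1, 100)
    me, mae, r = prediction_metrics(pred, obs)
    perm = rng.permutation(100)
    me2, mae2, r2 = prediction_metrics(pred[perm], obs[perm])
    assert (me, mae) == pytest.approx((me2, mae2), rel=1e-12)
    assert r == pytest.approx(r2, rel=1e-12)
    assert abs(me) <= mae


def test_direct_admin_estimates_pool_counts():
    admin = AdminHierarchy.rectangular(100.0, 1, 1)
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "cluster_id": ["A", "B"],
            "x": [10.0, 60.0], "y": [10.0, 60.0],
            "urban": False, "round": 2018, "indicator": "SBA",
            "events": [5, 15], "trials": [10, 20],
        }
    )
    ds = SurveyDataset(table)
    out = direct_admin_estimate(ds, "SBA", admin, level=1)
    assert out["direct"].iloc[0] == pytest.approx(20.0 / 30.0, rel=1e-12)
    # single-cluster unit at admin2 scale: that cluster's proportion
    admin2 = AdminHierarchy.rectangular(100.0, 1, 4)
    out2 = direct_admin_estimate(ds, "SBA", admin2, level=2).set_index("unit_id")
    assert out2.loc["D01P01", "direct"] == pytest.approx(0.5)
    # units without clusters flagged NaN, not dropped
    assert out2["direct"].isna().sum() == 2


def test_compare_admin_hand_example():
    modelled = pd.DataFrame({"unit_id": ["a", "b", "c"], "mean": [0.51, 0.48, 0.53]})
    direct = pd.DataFrame({"unit_id": ["a", "b", "c"], "direct": [0.50, 0.50, 0.50]})
    comp = compare_admin(modelled, direct)
    assert comp.mean_abs_difference == pytest.approx(0.02, rel=1e-12)
    assert comp.max_abs_difference == pytest.approx(0.03, rel=1e-12)
    assert comp.max_abs_unit == "c"
    ident = compare_admin(modelled, modelled.rename(columns={"mean": "direct"}))
    assert ident.mean_abs_difference == 0.0


def test_compare_admin_id_mismatch():
    a = pd.DataFrame({"unit_id": ["a"], "mean": [0.5]})
    b = pd.DataFrame({"unit_id": ["z"], "direct": [0.5]})
    with pytest.raises(ValueError, match="different units"):
        compare_admin(a, b)


def test_in_sample_error_not_worse_than_out_of_sample_on_average():
    """Averaged over replicate datasets, in-sample MAE does not exceed the
    K-fold out-of-sample MAE (direction sanity of the CV machinery)."""
    from geocci.covariates import CovariateMatrix

    diffs = []
    for rep in range(6):
        ds, X, coords, _ = simulate_gp_survey(
            n=160, beta=np.array([0.5, 0.9]), sigma_omega=0.5, range_rho=25.0,
            seed=700 + rep, mean_trials=5.0,
        )
        cm = CovariateMatrix(
            ds.clusters()["cluster_id"].to_numpy(), pd.DataFrame({"c1": X[:, 1]})
        )
        spec = ModelSpec(indicator="DPT3", n_samples=80, seed=rep,
                         engine_options={"maxfev": 50})
        oos = cross_validate(ds, cm, spec, make_folds(ds, "DPT3", K=2, seed=rep))
        ins = cross_validate(ds, cm, spec, make_folds(ds, "DPT3", K=1, seed=rep))
        diffs.append(oos.mae - ins.mae)
    assert np.mean(diffs) >= 0.0, diffs


def test_cross_validation_recovers_predictable_signal():
    """Out-of-sample CV on a well-specified simulation: near-zero bias and
    positive correlation; a strong-signal indicator validates better than a
    weak sparse one in most replicate datasets."""
    from geocci.covariates import CovariateMatrix

    wins = 0
    reps = 5
    for rep in range(reps):
        corr = {}
        for label, beta, presence, n in [
            ("strong", np.array([1.0, 1.2, -0.9]), 1.0, 260),
            ("weak", np.array([0.8, 0.08, -0.05]), 0.55, 260),
        ]:
            ds, X, coords, _ = simulate_gp_survey(
                n=n, beta=beta, sigma_omega=0.4 if label == "strong" else 0.7,
                range_rho=30.0, seed=100 + 17 * rep + (0 if label == "strong" else 1),
                mean_trials=6.0, presence=presence,
            )
            cm = CovariateMatrix(
                ds.clusters()["cluster_id"].to_numpy(),
                pd.DataFrame({"c1": X[:, 1], "c2": X[:, 2]}),
            )
            folds = make_folds(ds, "DPT3", K=2, seed=rep)
            spec = ModelSpec(indicator="DPT3", n_samples=100, seed=rep,
                             engine_options={"maxfev": 60})
            cv = cross_validate(ds, cm, spec, folds)
            assert abs(cv.mean_error) <= cv.mae
            corr[label] = cv.correlation
        if corr["strong"] > corr["weak"]:
            wins += 1
    assert wins >= reps - 1
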