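"""Out-of-sample cross-validation and modelled-vs-direct comparison.

Clusters are split into K folds (default 5) constrained so every fold keeps
at least 50 clusters with positive trials for the indicator under
validation.  For each fold the model is refit on the remaining folds and the
posterior-mean probability is predicted at the held-out cluster locations;
predicted values are compared with the observed cluster proportions through
bias (mean error), mean absolute error and Pearson correlation.

The comparator at admin1 level is the *direct* survey estimate: the pooled
proportion sum(events)/sum(trials) over the unit's clusters, with the eight
pooled proportions combined by the CCI formula when the index itself is
compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .admin import AdminHierarchy
from .cci import compute_cci
from .covariates import CovariateMatrix
from .model import ModelSpec, fit_indicator, predict_at_points
from .survey import INDICATORS, SurveyDataset

__all__ = [
    "FoldAssignment",
    "CVMetrics",
    "make_folds",
    "prediction_metrics",
    "cross_validate",
    "direct_admin_estimate",
    "direct_cci_estimate",
    "compare_admin",
]

MIN_FOLD_CLUSTERS = 50


@dataclass
class FoldAssignment:
    """cluster_id → fold index in {1..K}, with the eligibility record."""

    assignment: dict[str, int]
    K: int
    eligible_per_fold: dict[int, int]

    def fold_ids(self, fold: int) -> list[str]:
        return [c for c, f in self.assignment.items() if f == fold]


def make_folds(
    dataset: SurveyDataset,
    indicator: str,
    K: int = 5,
    seed: int = 0,
    min_per_fold: int = MIN_FOLD_CLUSTERS,
) -> FoldAssignment:
    """Random balanced partition of clusters into K folds.

    Balancing over clusters with positive trials guarantees the per-fold
    floor whenever it is feasible at all; infeasible inputs raise with the
    deficit.  K = 1 degenerates to a single fold (warned by caller usage).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    eligible = dataset.for_indicator(indicator)["cluster_id"].to_numpy()
    all_ids = dataset.clusters()["cluster_id"].to_numpy()
    if K > 1 and len(eligible) < K * min_per_fold:
        raise ValueError(
            f"indicator {indicator!r}: {len(eligible)} eligible clusters cannot "
            f"fill {K} folds of {min_per_fold} (deficit "
            f"{K * min_per_fold - len(eligible)})"
        )
    assignment: dict[str, int] = {}
    perm = rng.permutation(eligible)
    for f, chunk in enumerate(np.array_split(perm, K), start=1):
        for c in chunk:
            assignment[c] = f
    rest = np.asarray([c for c in all_ids if c not in assignment])
    if rest.size:
        folds = rng.integers(1, K + 1, size=rest.size)
        for c, f in zip(rest, folds):
            assignment[c] = int(f)
    counts = {f: 0 for f in range(1, K + 1)}
    for c in eligible:
        counts[assignment[c]] += 1
    return FoldAssignment(assignment, K, counts)


@dataclass
class CVMetrics:
    """Pooled cross-validation metrics over held-out clusters."""

    mean_error: float
    mae: float
    correlation: float
    n_clusters: int
    per_fold: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def __post_init__(self) -> None:
        if np.isfinite(self.mean_error) and abs(self.mean_error) > self.mae + 1e-12:
            raise ValueError("|mean error| cannot exceed MAE")


def prediction_metrics(pred, obs) -> tuple[float, float, float]:
    """(mean error, MAE, Pearson r) of predicted vs observed values."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    err = pred - obs
    me = float(err.mean())
    mae = float(np.abs(err).mean())
    if mae == 0.0:
        r = 1.0  # identical vectors: correlation 1 by definition
    elif len(pred) < 2 or np.std(pred) == 0 or np.std(obs) == 0:
        r = float("nan")
    else:
        r = float(stats.pearsonr(pred, obs)[0])
    return me, mae, r


def cross_validate(
    dataset: SurveyDataset,
    covariates: CovariateMatrix,
    spec: ModelSpec,
    folds: FoldAssignment,
) -> CVMetrics:
    """K-fold out-of-sample validation of one indicator's model.

    Each fold's model is trained on the other K−1 folds; the held-out
    prediction is the posterior mean of p at the cluster's reported
    location, compared with the observed proportion events/trials.
    """
    sub = dataset.for_indicator(spec.indicator)
    fold_of = sub["cluster_id"].map(folds.assignment)
    preds = np.full(len(sub), np.nan)
    rows = []
    for f in range(1, folds.K + 1):
        held = fold_of == f
        train_ids = sub.loc[~held, "cluster_id"]
        if folds.K == 1:  # degenerate: in-sample
            train_ids = sub["cluster_id"]
        try:
            fit = fit_indicator(dataset.subset_clusters(train_ids), covariates, spec)
        except Exception as exc:
            raise RuntimeError(f"fold {f}: model fit failed: {exc}") from exc
        test = sub[held] if folds.K > 1 else sub
        cov_rows = covariates.rows_for(test["cluster_id"])
        cols = fit.design_columns[1:]
        X_new = np.column_stack(
            [np.ones(len(test))] + [cov_rows[c].to_numpy() for c in cols]
        )
        p_samp = predict_at_points(
            fit, X_new, test[["x", "y"]].to_numpy(), seed=spec.seed + 100 + f
        )
        p_mean = p_samp.mean(axis=0)
        preds[np.flatnonzero(held if folds.K > 1 else np.ones(len(sub), bool))] = p_mean
        obs = (test["events"] / test["trials"]).to_numpy()
        me, mae, r = prediction_metrics(p_mean, obs)
        rows.append({"fold": f, "n": len(test), "mean_error": me, "mae": mae, "correlation": r})
    obs_all = (sub["events"] / sub["trials"]).to_numpy()
    me, mae, r = prediction_metrics(preds, obs_all)
    return CVMetrics(me, mae, r, len(sub), pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# direct (unmodelled) estimates and comparison
# ---------------------------------------------------------------------------

def direct_admin_estimate(
    dataset: SurveyDataset,
    indicator: str,
    admin: AdminHierarchy,
    level: int = 1,
) -> pd.DataFrame:
    """Pooled proportion sum(events)/sum(trials) per admin unit.

    Clusters are assigned by reported location.  Units without any cluster
    carrying trials are flagged with NaN, never silently dropped.
    """
    sub = dataset.for_indicator(indicator)
    labels = admin.assign_points(sub[["x", "y"]].to_numpy(), level=level)
    grouped = (
        pd.DataFrame(
            {"unit_id": labels, "events": sub["events"], "trials": sub["trials"]}
        )
        .groupby("unit_id")
        .sum()
    )
    all_units = admin.admin1_ids if level == 1 else admin.admin2_ids
    out = grouped.reindex(all_units)
    out["direct"] = out["events"] / out["trials"]
    out.index.name = "unit_id"
    return out.reset_index()[["unit_id", "events", "trials", "direct"]]


def direct_cci_estimate(
    dataset: SurveyDataset, admin: AdminHierarchy, level: int = 1
) -> pd.DataFrame:
    """CCI of the eight per-unit pooled indicator proportions."""
    parts = {
        name: direct_admin_estimate(dataset, name, admin, level).set_index("unit_id")[
            "direct"
        ]
        for name in INDICATORS
    }
    df = pd.DataFrame(parts)
    df["direct_cci"] = compute_cci({k: df[k].to_numpy() for k in INDICATORS})
    df.index.name = "unit_id"
    return df.reset_index()


@dataclass
class AdminComparison:
    table: pd.DataFrame
    mean_abs_difference: float
    max_abs_difference: float
    max_abs_unit: str


def compare_admin(modelled: pd.DataFrame, direct: pd.DataFrame) -> AdminComparison:
    """Per-unit modelled − direct differences and their summary.

    ``modelled`` needs columns unit_id and mean; ``direct`` needs unit_id
    and direct (or direct_cci).  Unit sets must match.
    """
    dcol = "direct_cci" if "direct_cci" in direct.columns else "direct"
    m = modelled.set_index("unit_id")["mean"]
    d = direct.set_index("unit_id")[dcol]
    if set(m.index) != set(d.index):
        raise ValueError("modelled and direct tables cover different units")
    d = d.reindex(m.index)
    diff = (m - d).rename("difference")
    tab = pd.DataFrame({"modelled": m, "direct": d, "difference": diff}).reset_index()
    abs_diff = diff.abs()
    worst = abs_diff.idxmax()
    return AdminComparison(
        table=tab,
        mean_abs_difference=float(abs_diff.mean()),
        max_abs_difference=float(abs_diff.max()),
        max_abs_unit=str(worst),
    )
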