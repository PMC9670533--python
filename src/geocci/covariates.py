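"""Covariate extraction and the two-stage covariate selection.

Extraction is displacement-aware: cluster coordinates are randomly displaced
(up to 2 km urban / 5 km rural), so a covariate value is the mean of raster
cells whose centers fall within the matching 2 km or 5 km disc around the
reported location.

Selection proceeds in three steps, per indicator:

1. *Fractional-polynomial search* — for each candidate covariate, the best
   power transform among first-order powers {-2, -1, -0.5, 0, 0.5, 1, 2, 3}
   (0 meaning log) and all second-order pairs, judged by binomial-logistic
   deviance with Royston-style closed testing so that needless complexity is
   not kept.
2. *Collinearity pruning* — among pairs with Pearson |r| > 0.8, keep the
   member with the stronger single-covariate association to the outcome
   (absolute Wald z), iterating until no pair exceeds the threshold.
3. *Backward elimination* — iteratively drop the covariate with the largest
   Wald p while that p exceeds 0.05.

Selection regressions are unweighted cluster-level binomial logistic fits
(events/trials); spatial correlation enters later, in the geostatistical
model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .grid import RasterGrid
from .model import NonConvergenceError

__all__ = [
    "FP_POWERS",
    "ColumnTransform",
    "CovariateMatrix",
    "SelectionReport",
    "buffer_extract",
    "extract_covariates",
    "fractional_polynomial_candidates",
    "select_best_fp",
    "prune_collinear",
    "backward_eliminate",
    "select_covariates",
]

FP_POWERS: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)

URBAN_RADIUS_KM = 2.0
RURAL_RADIUS_KM = 5.0


# ---------------------------------------------------------------------------
# buffer extraction
# ---------------------------------------------------------------------------

def buffer_extract(
    raster: RasterGrid,
    point: Sequence[float],
    urban: bool,
    urban_radius: float = URBAN_RADIUS_KM,
    rural_radius: float = RURAL_RADIUS_KM,
) -> float:
    """Mean of raster cells whose centers fall within the displacement disc.

    The disc radius is 2 km for urban clusters and 5 km for rural ones,
    matching the maximum coordinate displacement.  If no cell center falls
    inside the disc (cells coarser than the buffer), the containing cell's
    value is returned.  Nodata cells are excluded from the mean; if the whole
    buffer is nodata the nearest valid cell's value is used.
    """
    x, y = float(point[0]), float(point[1])
    radius = urban_radius if urban else rural_radius
    centers = raster.cell_centers()
    vals = raster.values.ravel()
    d2 = (centers[:, 0] - x) ** 2 + (centers[:, 1] - y) ** 2
    inside = d2 <= radius**2
    if inside.any():
        sel = vals[inside]
        good = np.isfinite(sel)
        if good.any():
            return float(sel[good].mean())
    v = float(raster.value_at(x, y))
    if np.isfinite(v):
        return v
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("raster has no valid cells")
    return float(vals[finite][np.argmin(d2[finite])])


def extract_covariates(
    rasters: Mapping[str, RasterGrid],
    clusters: pd.DataFrame,
    urban_radius: float = URBAN_RADIUS_KM,
    rural_radius: float = RURAL_RADIUS_KM,
) -> pd.DataFrame:
    """Raw covariate values per cluster via buffered extraction.

    ``clusters`` needs columns cluster_id, x, y, urban.  Returns a frame
    indexed like ``clusters`` with one column per raster.
    """
    out = {"cluster_id": clusters["cluster_id"].to_numpy()}
    for name, rast in rasters.items():
        out[name] = [
            buffer_extract(rast, (r.x, r.y), bool(r.urban), urban_radius, rural_radius)
            for r in clusters.itertuples()
        ]
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# fractional polynomials
# ---------------------------------------------------------------------------

@dataclass
class ColumnTransform:
    """One design column: an FP power of a (shifted) source covariate,
    standardized.  ``power = 0`` means the natural log; ``repeated`` marks
    the second column of a repeated-power pair, x^p * ln(x)."""

    name: str
    source: str
    power: float
    repeated: bool = False
    shift: float = 0.0
    center: float = 0.0
    scale: float = 1.0
    #: lower clamp of the transform domain — values below the training
    #: support (e.g. raster cells outside the cluster range) are clamped
    #: rather than rejected at prediction time
    floor: float = 0.0

    def raw(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float) + self.shift
        if self.floor > 0:
            x = np.maximum(x, self.floor)
        if np.any(x <= 0):
            raise ValueError(f"{self.source}: non-positive values after shift")
        lx = np.log(x)
        t = lx if self.power == 0 else x**self.power
        if self.repeated:
            t = t * lx
        return t

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (self.raw(x) - self.center) / self.scale


def positivity_shift(x: np.ndarray) -> float:
    """Shift making a covariate strictly positive before FP transforms.

    Zero if already positive; otherwise -min(x) plus a small fraction of the
    range (or 1 for a constant column)."""
    x = np.asarray(x, dtype=float)
    mn, mx = float(np.min(x)), float(np.max(x))
    if mn > 0:
        return 0.0
    span = mx - mn
    return -mn + (0.01 * span if span > 0 else 1.0)


def _fp_columns(x: np.ndarray, powers: Sequence[float]) -> np.ndarray:
    """Design columns for an FP power vector (repeats → multiply by log)."""
    lx = np.log(x)
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        base = lx if p == 0 else x**p
        k = seen.get(p, 0)
        cols.append(base * lx**k)
        seen[p] = k + 1
    return np.column_stack(cols)


def fractional_polynomial_candidates(x: np.ndarray) -> list[tuple[tuple[float, ...], np.ndarray]]:
    """All first- and second-order FP candidates for a positive vector.

    Returns (powers, columns) pairs: 8 first-order transforms and the 36
    unordered second-order pairs, with a repeated power (p, p) meaning
    (x^p, x^p ln x).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("fractional polynomials need strictly positive values")
    out: list[tuple[tuple[float, ...], np.ndarray]] = []
    for p in FP_POWERS:
        out.append(((p,), _fp_columns(x, (p,))))
    for i, p in enumerate(FP_POWERS):
        for q in FP_POWERS[i:]:
            out.append(((p, q), _fp_columns(x, (p, q))))
    return out


def _fit_glm(events, trials, cols):
    """Binomial logistic fit; cols may be None (intercept only) or 2-D."""
    events = np.asarray(events, dtype=float)
    trials = np.asarray(trials, dtype=float)
    endog = np.column_stack([events, trials - events])
    if cols is None:
        exog = np.ones((len(events), 1))
    else:
        cols = np.atleast_2d(np.asarray(cols, dtype=float))
        if cols.shape[0] != len(events):
            cols = cols.T
        exog = np.column_stack([np.ones(len(events)), cols])
    model = sm.GLM(endog, exog, family=sm.families.Binomial())
    return model.fit()


@dataclass
class FPResult:
    source: str
    powers: tuple[float, ...]
    shift: float
    deviance: float
    deviance_linear: float
    deviance_null: float
    weak: bool
    separation: bool = False


def select_best_fp(
    events,
    trials,
    x: np.ndarray,
    source: str = "x",
    alpha: float = 0.05,
    shift: float | None = None,
) -> FPResult:
    """Best fractional-polynomial transform for one covariate.

    Closed testing in the Royston function-selection style: the best
    second-order FP must beat the best first-order one at a chi-squared
    2-df test to be kept, and the best first-order must beat the linear
    term at 1 df, so the linear transform wins unless the data demand
    curvature.  A covariate whose best transform does not improve on the
    intercept-only model at 1 df is flagged as weak (and left linear).
    Perfect separation is flagged and the linear transform returned.
    """
    x = np.asarray(x, dtype=float)
    if shift is None:
        shift = positivity_shift(x)
    xs = np.maximum(x + shift, 1e-12)
    try:
        cands = fractional_polynomial_candidates(xs)
        dev_null = _fit_glm(events, trials, None).deviance
        best1: tuple[float, tuple[float, ...]] | None = None
        best2: tuple[float, tuple[float, ...]] | None = None
        dev_lin = np.inf
        for powers, cols in cands:
            if not np.all(np.isfinite(cols)):
                continue
            try:
                dev = _fit_glm(events, trials, cols).deviance
            except Exception:
                continue
            if not np.isfinite(dev):
                continue
            if powers == (1.0,):
                dev_lin = dev
            store = (dev, powers)
            if len(powers) == 1:
                if best1 is None or dev < best1[0]:
                    best1 = store
            else:
                if best2 is None or dev < best2[0]:
                    best2 = store
    except Exception:
        return FPResult(source, (1.0,), shift, np.nan, np.nan, np.nan, weak=True, separation=True)

    if best1 is None:
        return FPResult(source, (1.0,), shift, np.nan, np.nan, dev_null, weak=True, separation=True)

    chosen = best1
    # FP2 must earn its extra complexity over FP1 (2 df)
    if best2 is not None and (best1[0] - best2[0]) > chi2.ppf(1 - alpha, 2):
        chosen = best2
    # FP1 must earn curvature over the linear term (1 df)
    elif np.isfinite(dev_lin) and (dev_lin - best1[0]) <= chi2.ppf(1 - alpha, 1):
        chosen = (dev_lin, (1.0,))
    weak = (dev_null - chosen[0]) <= chi2.ppf(1 - alpha, 1)
    if weak:
        chosen = (dev_lin if np.isfinite(dev_lin) else chosen[0], (1.0,))
    return FPResult(
        source=source, powers=chosen[1], shift=shift, deviance=float(chosen[0]),
        deviance_linear=float(dev_lin), deviance_null=float(dev_null), weak=bool(weak),
    )


# ---------------------------------------------------------------------------
# covariate matrix
# ---------------------------------------------------------------------------

@dataclass
class CovariateMatrix:
    """Transformed, standardized design columns aligned to clusters."""

    cluster_ids: np.ndarray
    data: pd.DataFrame
    transforms: list[ColumnTransform] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.cluster_ids) != len(self.data):
            raise ValueError("cluster_ids and data length mismatch")
        if self.data.isna().any().any():
            raise ValueError("covariate matrix contains missing values")
        self._index = pd.Index(self.cluster_ids)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def rows_for(self, cluster_ids) -> pd.DataFrame:
        pos = self._index.get_indexer(cluster_ids)
        if (pos < 0).any():
            raise KeyError("cluster ids missing from covariate matrix")
        return self.data.iloc[pos].reset_index(drop=True)

    def drop(self, columns: Sequence[str]) -> "CovariateMatrix":
        keep = [c for c in self.data.columns if c not in set(columns)]
        return CovariateMatrix(
            self.cluster_ids,
            self.data[keep].copy(),
            [t for t in self.transforms if t.name in keep],
        )

    def to_csv(self, path: str | Path) -> None:
        df = self.data.copy()
        df.insert(0, "cluster_id", self.cluster_ids)
        df.to_csv(path, index=False)


def build_covariate_matrix(
    raw: pd.DataFrame, fp_results: Mapping[str, FPResult]
) -> CovariateMatrix:
    """Apply chosen FP transforms to raw per-cluster values and standardize."""
    ids = raw["cluster_id"].to_numpy()
    cols: dict[str, np.ndarray] = {}
    transforms: list[ColumnTransform] = []
    for source, res in fp_results.items():
        x = raw[source].to_numpy(dtype=float)
        seen: dict[float, int] = {}
        for p in res.powers:
            k = seen.get(p, 0)
            seen[p] = k + 1
            xs_min = float(np.min(x) + res.shift)
            t = ColumnTransform(
                name=f"{source}__fp{p:g}" + ("_log" if k else ""),
                source=source, power=p, repeated=bool(k), shift=res.shift,
                floor=0.5 * xs_min,
            )
            col = t.raw(x)
            t.center = float(col.mean())
            sd = float(col.std(ddof=0))
            t.scale = sd if sd > 0 else 1.0
            cols[t.name] = (col - t.center) / t.scale
            transforms.append(t)
    return CovariateMatrix(ids, pd.DataFrame(cols), transforms)


# ---------------------------------------------------------------------------
# pruning and backward elimination
# ---------------------------------------------------------------------------

def association_scores(events, trials, matrix: CovariateMatrix) -> dict[str, float]:
    """Absolute Wald z of each column's single-covariate binomial fit."""
    scores = {}
    for c in matrix.columns:
        try:
            res = _fit_glm(events, trials, matrix.data[c].to_numpy())
            scores[c] = float(abs(res.tvalues[1]))
        except Exception:
            scores[c] = 0.0
    return scores


def prune_collinear(
    matrix: CovariateMatrix,
    scores: Mapping[str, float],
    threshold: float = 0.8,
) -> tuple[CovariateMatrix, list[tuple[str, str, float]]]:
    """Drop the weaker member of every pair with Pearson |r| > threshold.

    Applied iteratively (weakest victim first) until no pair exceeds the
    threshold.  Returns the pruned matrix and a log of
    (dropped, kept_partner, r) tuples.
    """
    dropped: list[tuple[str, str, float]] = []
    current = matrix
    while True:
        cols = current.columns
        if len(cols) < 2:
            break
        corr = current.data.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        over = np.argwhere(corr > threshold)
        if not len(over):
            break
        # among all offending pairs, remove the lowest-score column involved
        involved = sorted(
            {cols[i] for i, j in over},
            key=lambda c: (scores.get(c, 0.0), c),
        )
        victim = involved[0]
        vi = cols.index(victim)
        partner_j = int(np.argmax(corr[vi]))
        dropped.append((victim, cols[partner_j], float(corr[vi, partner_j])))
        current = current.drop([victim])
    return current, dropped


@dataclass
class SelectionReport:
    """Full record of covariate selection for one indicator."""

    indicator: str
    fp_choices: dict[str, FPResult]
    pruned: list[tuple[str, str, float]]
    elimination_trace: list[tuple[str, float]]
    final_covariates: list[str]
    final_pvalues: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "indicator": self.indicator,
            "fp_choices": {k: asdict(v) for k, v in self.fp_choices.items()},
            "pruned": self.pruned,
            "elimination_trace": self.elimination_trace,
            "final_covariates": self.final_covariates,
            "final_pvalues": self.final_pvalues,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def backward_eliminate(
    events,
    trials,
    matrix: CovariateMatrix,
    alpha: float = 0.05,
) -> tuple[CovariateMatrix, list[tuple[str, float]], dict[str, float]]:
    """Stepwise backward elimination on Wald p-values.

    Refit the full binomial logistic model, drop the covariate with the
    largest p while that p exceeds ``alpha``; stop when all retained
    covariates have p <= alpha.  The empty model is allowed.  Returns the
    reduced matrix, the elimination trace [(dropped, p), ...] and the final
    p-values.
    """
    current = matrix
    trace: list[tuple[str, float]] = []
    while current.columns:
        cols = current.columns
        try:
            res = _fit_glm(events, trials, current.data.to_numpy())
        except Exception as exc:
            raise NonConvergenceError(
                f"binomial logistic fit failed with covariates {cols}: {exc}"
            ) from exc
        pvals = dict(zip(cols, res.pvalues[1:]))
        worst = max(pvals, key=lambda c: (pvals[c], c))
        if pvals[worst] <= alpha:
            return current, trace, {c: float(p) for c, p in pvals.items()}
        trace.append((worst, float(pvals[worst])))
        current = current.drop([worst])
    return current, trace, {}


def select_covariates(
    dataset,
    indicator: str,
    rasters: Mapping[str, RasterGrid] | None = None,
    raw: pd.DataFrame | None = None,
    alpha: float = 0.05,
    corr_threshold: float = 0.8,
    min_clusters: int = 30,
) -> tuple[CovariateMatrix, SelectionReport]:
    """Run the full two-stage selection for one indicator.

    Provide either covariate ``rasters`` (buffer-extracted here) or a
    pre-extracted ``raw`` frame with a cluster_id column.  Returns the final
    covariate matrix (restricted to selected columns, aligned to *all*
    clusters in ``raw``) and the selection report.
    """
    sub = dataset.for_indicator(indicator)
    if len(sub) < min_clusters:
        raise ValueError(
            f"indicator {indicator!r}: {len(sub)} clusters with trials > 0 "
            f"(need >= {min_clusters}) for covariate selection"
        )
    if raw is None:
        if rasters is None:
            raise ValueError("need rasters or a raw covariate frame")
        raw = extract_covariates(rasters, dataset.clusters())
    events = sub["events"].to_numpy(float)
    trials = sub["trials"].to_numpy(float)
    raw_idx = pd.Index(raw["cluster_id"])
    pos = raw_idx.get_indexer(sub["cluster_id"])
    sources = [c for c in raw.columns if c != "cluster_id"]

    # the positivity shift is computed on the full covariate column so the
    # transform domain covers every cluster, not just this indicator's
    fp_choices = {
        s: select_best_fp(
            events, trials, raw[s].to_numpy(float)[pos], source=s, alpha=alpha,
            shift=positivity_shift(raw[s].to_numpy(float)),
        )
        for s in sources
    }
    full = build_covariate_matrix(raw, fp_choices)
    sub_matrix = CovariateMatrix(
        sub["cluster_id"].to_numpy(), full.rows_for(sub["cluster_id"]), full.transforms
    )
    scores = association_scores(events, trials, sub_matrix)
    pruned_matrix, pruned_log = prune_collinear(sub_matrix, scores, corr_threshold)
    final_matrix, trace, pvals = backward_eliminate(events, trials, pruned_matrix, alpha)
    report = SelectionReport(
        indicator=indicator,
        fp_choices=fp_choices,
        pruned=pruned_log,
        elimination_trace=trace,
        final_covariates=final_matrix.columns,
        final_pvalues=pvals,
    )
    selected_full = CovariateMatrix(
        full.cluster_ids,
        full.data[final_matrix.columns].copy(),
        [t for t in full.transforms if t.name in set(final_matrix.columns)],
    )
    return selected_full, report
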