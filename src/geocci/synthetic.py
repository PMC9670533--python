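"""Fully synthetic study generator with known ground truth.

Emulates the structure of a two-round national household survey feeding the
CCI mapping pipeline: a square region gridded into 5 km cells, a two-level
admin hierarchy, a right-skewed population surface, smooth covariate
surfaces, a latent Matérn field, and displaced survey clusters with binomial
counts for the eight CCI indicators.

Default parameters reproduce the pooled study conditions: 2 survey rounds of
3,254 clusters each (6,508 total), per-indicator denominators and presence
probabilities matching the pooled sample description (from ~24.5k
individuals over 6,383 clusters for skilled birth attendance down to ~2.0k
individuals over 1,639 clusters for care-seeking), national coverage levels
matching the published national estimates, displacement up to 2 km urban /
5 km rural, and 25 admin1 units each split into 8 admin2 units.  The spatial
extent is a 200 km square of 40×40 cells — a scaled extent with realistic
cluster density rather than a continental-scale grid.

The nugget (non-spatial cluster-level residual) is applied per cluster at
sampling time; the stored true surface is the nugget-free p(s), which is the
models' prediction target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.spatial.distance import cdist
from scipy.special import expit, logit

from .admin import AdminHierarchy
from .grid import RasterGrid
from .model import SpatialEffectParams, matern_covariance, _matern_corr_matrix
from .survey import INDICATORS, SurveyDataset

__all__ = [
    "IndicatorSpec",
    "SyntheticConfig",
    "TrueField",
    "SyntheticBundle",
    "default_indicator_specs",
    "simulate_gaussian_field",
    "simulate_population",
    "build_true_surfaces",
    "sample_clusters",
    "displace_location",
    "generate",
]

#: Pooled two-round sample description per indicator:
#: (clusters with data, individuals, national coverage %).
SAMPLE_DESCRIPTION: dict[str, tuple[int, int, float]] = {
    "SBA": (6383, 24513, 94.6),
    "ANC4": (6383, 24141, 96.3),
    "DFPSm": (5296, 12059, 65.5),
    "DPT3": (4861, 8706, 85.3),
    "BCG": (4861, 8706, 95.3),
    "MSL": (4861, 8706, 80.0),
    "ORS": (3301, 5014, 33.6),
    "CAREP": (1639, 1956, 70.1),
}

_TOTAL_CLUSTERS = 6508  # 3,254 enumeration areas per round, two rounds

MAX_DISPLACEMENT_URBAN_KM = 2.0
MAX_DISPLACEMENT_RURAL_KM = 5.0


@dataclass(frozen=True)
class IndicatorSpec:
    """Sampling structure of one indicator.

    mean_trials_per_cluster : mean denominator among clusters that have any
        eligible individuals (zero-truncated Poisson mean).
    cluster_presence_prob : probability a cluster has eligible individuals
        at all — sparse indicators such as care-seeking for pneumonia only
        appear in a quarter of clusters.
    intercept : national coverage level on the logit scale.
    """

    name: str
    mean_trials_per_cluster: float
    cluster_presence_prob: float
    intercept: float

    def __post_init__(self) -> None:
        if self.name not in INDICATORS:
            raise ValueError(f"unknown indicator {self.name!r}")
        if self.mean_trials_per_cluster < 1.0:
            raise ValueError("zero-truncated trial counts have mean >= 1")
        if not 0 < self.cluster_presence_prob <= 1:
            raise ValueError("cluster_presence_prob must be in (0, 1]")


def default_indicator_specs() -> list[IndicatorSpec]:
    """Specs matching the pooled survey's per-indicator sample structure."""
    specs = []
    for name in INDICATORS:
        n_clusters, n_individuals, coverage_pct = SAMPLE_DESCRIPTION[name]
        specs.append(
            IndicatorSpec(
                name=name,
                mean_trials_per_cluster=n_individuals / n_clusters,
                cluster_presence_prob=n_clusters / _TOTAL_CLUSTERS,
                intercept=float(logit(coverage_pct / 100.0)),
            )
        )
    return specs


#: Covariate effects per indicator on standardized smooth surfaces
#: (travel_time, women_education, improved_sanitation).  Strong signal for
#: the near-universal pregnancy indicators, weak for care-seeking — the
#: qualitative predictability ordering seen in national data.
DEFAULT_BETA_TRUE: dict[str, tuple[float, ...]] = {
    "DFPSm": (-0.40, 0.60, 0.30),
    "ANC4": (-0.70, 0.50, 0.30),
    "SBA": (-0.90, 0.50, 0.40),
    "BCG": (-0.30, 0.30, 0.40),
    "DPT3": (-0.30, 0.30, 0.30),
    "MSL": (-0.25, 0.25, 0.30),
    "ORS": (-0.30, 0.20, 0.40),
    "CAREP": (-0.10, 0.10, 0.05),
}

#: Correlation ranges (km) of the smooth covariate surfaces.
DEFAULT_COVARIATE_RANGES: dict[str, float] = {
    "travel_time": 80.0,
    "women_education": 60.0,
    "improved_sanitation": 100.0,
}


@dataclass
class SyntheticConfig:
    """Ground-truth configuration for a synthetic study."""

    seed: int = 0
    region_size_km: float = 200.0
    cell_km: float = 5.0
    n_admin1: int = 25
    n_admin2_per_admin1: int = 8
    n_clusters: int = _TOTAL_CLUSTERS
    urban_fraction: float = 0.6
    indicators: list[IndicatorSpec] = field(default_factory=default_indicator_specs)
    field_params: SpatialEffectParams = field(
        default_factory=lambda: SpatialEffectParams(
            sigma_omega=0.5, range_rho=50.0, nu=1.0, sigma_eps=0.3
        )
    )
    beta_true: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_BETA_TRUE)
    )
    covariate_ranges: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_RANGES)
    )
    total_population: float = 31e6
    displacement: bool = True

    def __post_init__(self) -> None:
        n = self.region_size_km / self.cell_km
        if abs(n - round(n)) > 1e-9:
            raise ValueError("region_size_km must be a whole number of cells")
        if self.n_admin1 * self.n_admin2_per_admin1 < 1:
            raise ValueError("need at least one admin unit")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not 0 <= self.urban_fraction <= 1:
            raise ValueError("urban_fraction must be in [0, 1]")
        names = [s.name for s in self.indicators]
        if sorted(names) != sorted(INDICATORS):
            raise ValueError(
                "indicators must be exactly the eight CCI components, once each"
            )
        for name, beta in self.beta_true.items():
            if len(beta) != len(self.covariate_ranges):
                raise ValueError(
                    f"beta_true[{name!r}] has {len(beta)} coefficients for "
                    f"{len(self.covariate_ranges)} covariates"
                )

    @property
    def n_side(self) -> int:
        return round(self.region_size_km / self.cell_km)

    def grid_template(self) -> RasterGrid:
        n = self.n_side
        return RasterGrid(np.zeros((n, n)), 0.0, 0.0, self.cell_km)


@dataclass
class TrueField:
    """Ground-truth surfaces: per-indicator nugget-free coverage, the shared
    spatial-effect realization, covariates and population."""

    p_true: dict[str, RasterGrid]
    omega_true: RasterGrid
    covariates: dict[str, RasterGrid]
    population: RasterGrid

    def national_coverage(self, indicator: str) -> float:
        """Population-weighted mean of the true surface."""
        w = self.population.values.ravel()
        p = self.p_true[indicator].values.ravel()
        return float(np.sum(w * p) / np.sum(w))


@dataclass
class SyntheticBundle:
    config: SyntheticConfig
    field: TrueField
    admin: AdminHierarchy
    dataset: SurveyDataset

    def write(self, out_dir: str | Path) -> None:
        """Write the bundle as text artifacts with a YAML manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {}
        self.dataset.to_csv(out / "clusters.csv")
        files["clusters"] = "clusters.csv"
        if self.dataset.true_locations is not None:
            self.dataset.true_locations.to_csv(out / "true_locations.csv", index=False)
            files["true_locations"] = "true_locations.csv"
        self.admin.to_geojson(out / "admin.geojson")
        files["admin"] = "admin.geojson"
        self.field.population.write_ascii(out / "population.asc")
        files["population"] = "population.asc"
        files["covariates"] = {}
        for name, rast in self.field.covariates.items():
            rast.write_ascii(out / f"cov_{name}.asc")
            files["covariates"][name] = f"cov_{name}.asc"
        files["true_surfaces"] = {}
        for name, rast in self.field.p_true.items():
            rast.write_ascii(out / f"true_{name}.asc")
            files["true_surfaces"][name] = f"true_{name}.asc"
        self.field.omega_true.write_ascii(out / "true_omega.asc")
        files["omega"] = "true_omega.asc"
        manifest = {
            "seed": self.config.seed,
            "region_size_km": self.config.region_size_km,
            "cell_km": self.config.cell_km,
            "n_clusters": self.config.n_clusters,
            "files": files,
        }
        (out / "manifest.yaml").write_text(yaml.safe_dump(manifest))


# ---------------------------------------------------------------------------
# field and population simulation
# ---------------------------------------------------------------------------

def simulate_gaussian_field(
    grid: RasterGrid, params: SpatialEffectParams, seed: int | np.random.Generator
) -> RasterGrid:
    """One realization of a zero-mean stationary Matérn Gaussian field.

    The covariance between cells at distance d is
    ``matern_covariance(d, params)`` (the nugget is *not* added).  Dense
    Cholesky simulation — intended for grids up to a few thousand cells.
    """
    if grid.n_cells < 4:
        raise ValueError("grid must have at least 4 cells")
    params = SpatialEffectParams(
        params.sigma_omega, params.range_rho, params.nu, params.sigma_eps
    )  # re-validates
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    centers = grid.cell_centers()
    D = cdist(centers, centers)
    C = params.sigma_omega**2 * _matern_corr_matrix(D, params.range_rho, params.nu)
    C[np.diag_indices_from(C)] += 1e-10 * params.sigma_omega**2 + 1e-300
    L = np.linalg.cholesky(C)
    z = rng.standard_normal(grid.n_cells)
    return grid.like(L @ z)


def simulate_population(
    grid: RasterGrid,
    seed: int | np.random.Generator,
    total: float = 31e6,
    range_km: float = 60.0,
    log_sd: float = 1.5,
) -> RasterGrid:
    """Strictly positive, right-skewed population surface.

    An exponentiated smooth Gaussian field normalized to ``total`` — a
    caricature of settlement patterns with dense pockets and empty backlands.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    f = simulate_gaussian_field(
        grid, SpatialEffectParams(sigma_omega=1.0, range_rho=range_km), rng
    )
    raw = np.exp(log_sd * f.values)
    return grid.like(raw * (total / raw.sum()))


def build_true_surfaces(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> TrueField:
    """Generate covariates, the shared spatial field, population and the
    nugget-free true coverage surface per indicator:
    ``p = logit^{-1}(intercept + X beta_true + omega)``.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    grid = config.grid_template()
    covariates: dict[str, RasterGrid] = {}
    for name, rng_km in config.covariate_ranges.items():
        f = simulate_gaussian_field(
            grid, SpatialEffectParams(1.0, rng_km, config.field_params.nu), rng
        )
        v = f.values.ravel()
        covariates[name] = grid.like((v - v.mean()) / (v.std() or 1.0))
    omega = simulate_gaussian_field(
        grid,
        SpatialEffectParams(
            config.field_params.sigma_omega,
            config.field_params.range_rho,
            config.field_params.nu,
        ),
        rng,
    )
    population = simulate_population(grid, rng, total=config.total_population)
    X = np.column_stack([covariates[n].values.ravel() for n in config.covariate_ranges])
    p_true: dict[str, RasterGrid] = {}
    specs = {s.name: s for s in config.indicators}
    for name in INDICATORS:
        beta = np.asarray(config.beta_true[name], dtype=float)
        if beta.shape[0] != X.shape[1]:
            raise ValueError(f"beta_true[{name!r}] does not match covariate count")
        eta = specs[name].intercept + X @ beta + omega.values.ravel()
        p_true[name] = grid.like(expit(eta))
    return TrueField(p_true, omega, covariates, population)


# ---------------------------------------------------------------------------
# cluster sampling
# ---------------------------------------------------------------------------

def displace_location(
    point: tuple[float, float],
    urban: bool,
    rng: np.random.Generator,
    region_size_km: float,
    max_urban: float = MAX_DISPLACEMENT_URBAN_KM,
    max_rural: float = MAX_DISPLACEMENT_RURAL_KM,
) -> tuple[float, float]:
    """Random displacement at a uniform angle and U[0, max] radius,
    clipped to the region square."""
    r_max = max_urban if urban else max_rural
    r = rng.uniform(0.0, r_max)
    a = rng.uniform(0.0, 2 * np.pi)
    x = float(np.clip(point[0] + r * np.cos(a), 0.0, region_size_km))
    y = float(np.clip(point[1] + r * np.sin(a), 0.0, region_size_km))
    return x, y


def _ztp_rate(mean: float) -> float:
    """Rate of the zero-truncated Poisson with the given mean."""
    if mean <= 1.0:
        return 1e-9
    return brentq(lambda lam: lam / (1 - np.exp(-lam)) - mean, 1e-9, 10 * mean)


def _sample_ztp(lam: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-truncated Poisson draws by rejection of zeros."""
    out = rng.poisson(lam, size)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, int(zero.sum()))
        zero = out == 0
    return out


def sample_clusters(
    field: TrueField,
    config: SyntheticConfig,
    seed: int | np.random.Generator,
) -> SurveyDataset:
    """Draw displaced survey clusters with binomial indicator counts.

    Cluster locations are sampled proportional to cell population (uniform
    within the cell); the most populous cells host the urban clusters.  For
    each indicator, trials follow presence thinning × a zero-truncated
    Poisson, and events are binomial at the true cell probability with a
    cluster-level nugget added on the logit scale.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pop = field.population.values.ravel()
    if pop.sum() <= 0 or np.any(pop < 0):
        raise ValueError("population must be non-negative with positive total")
    grid = field.population
    n = config.n_clusters
    cells = rng.choice(grid.n_cells, size=n, p=pop / pop.sum())
    centers = grid.cell_centers()
    half = grid.cell_km / 2.0
    xs = centers[cells, 0] + rng.uniform(-half, half, n)
    ys = centers[cells, 1] + rng.uniform(-half, half, n)

    # urban flag: clusters in the most populous cells, matching the target
    # fraction; random jitter breaks ties between clusters sharing a cell
    order = np.argsort(pop[cells] + rng.uniform(0, 1e-6, n))[::-1]
    n_urban = int(round(config.urban_fraction * n))
    urban = np.zeros(n, dtype=bool)
    urban[order[:n_urban]] = True

    rounds = np.where(np.arange(n) % 2 == 0, 2018, 2019)
    ids = np.array([f"C{k:05d}" for k in range(n)])

    rows = []
    specs = {s.name: s for s in config.indicators}
    sigma_eps = config.field_params.sigma_eps
    for name in INDICATORS:
        spec = specs[name]
        present = rng.uniform(size=n) < spec.cluster_presence_prob
        trials = np.zeros(n, dtype=int)
        if present.any():
            lam = _ztp_rate(spec.mean_trials_per_cluster)
            trials[present] = _sample_ztp(lam, int(present.sum()), rng)
        p_cell = field.p_true[name].value_at(xs, ys)
        eps = rng.normal(0.0, sigma_eps, n) if sigma_eps > 0 else np.zeros(n)
        p_cluster = expit(logit(np.clip(p_cell, 1e-12, 1 - 1e-12)) + eps)
        events = rng.binomial(trials, p_cluster)
        rows.append(
            pd.DataFrame(
                {
                    "cluster_id": ids,
                    "indicator": name,
                    "events": events,
                    "trials": trials,
                }
            )
        )

    reported = np.empty((n, 2))
    for i in range(n):
        if config.displacement:
            reported[i] = displace_location(
                (xs[i], ys[i]), bool(urban[i]), rng, config.region_size_km
            )
        else:
            reported[i] = (xs[i], ys[i])

    meta = pd.DataFrame(
        {
            "cluster_id": ids,
            "x": reported[:, 0],
            "y": reported[:, 1],
            "urban": urban,
            "round": rounds,
        }
    )
    long = pd.concat(rows, ignore_index=True).merge(meta, on="cluster_id")
    true_loc = pd.DataFrame({"cluster_id": ids, "x_true": xs, "y_true": ys})
    return SurveyDataset(long[["cluster_id", "x", "y", "urban", "round",
                               "indicator", "events", "trials"]], true_loc)


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Full synthetic study: surfaces, admin hierarchy and survey dataset."""
    rng = np.random.default_rng(config.seed)
    field = build_true_surfaces(config, rng)
    admin = AdminHierarchy.rectangular(
        config.region_size_km, config.n_admin1, config.n_admin2_per_admin1
    )
    dataset = sample_clusters(field, config, rng)
    return SyntheticBundle(config, field, admin, dataset)
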