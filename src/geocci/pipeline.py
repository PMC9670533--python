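"""End-to-end pipeline: simulate → select covariates → fit ×8 → predict →
combine CCI → aggregate → validate.

Every stage boundary is a file with a documented schema (CSV, GeoJSON, ESRI
ASCII rasters, YAML config, JSON reports) and the whole run is driven by a
single global seed.  Per-stage seeds are spawned from the global seed with
``numpy.random.SeedSequence`` so adding stages never shifts earlier streams.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .admin import AdminHierarchy
from .aggregate import (
    aggregate_population_weighted,
    nested_consistency_check,
    summarize_stack,
)
from .cci import combine_posterior_stacks
from .covariates import select_covariates
from .grid import RasterGrid
from .model import ModelSpec, PriorSpec, fit_indicator, predict_surface
from .survey import INDICATORS, SurveyDataset
from .validation import (
    compare_admin,
    cross_validate,
    direct_cci_estimate,
    make_folds,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "demo_config"]

log = logging.getLogger("geocci")


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    In synthetic mode (the default) the generator parameters live in
    ``synthetic_overrides``; in real mode, paths to clusters CSV, covariate
    rasters, population raster and admin GeoJSON are given instead.
    """

    out_dir: str = "geocci_run"
    seed: int = 0
    n_posterior_samples: int = 1000
    cv_folds: int = 5
    cv_indicators: list[str] = field(default_factory=list)
    engine: str = "laplace"
    synthetic: bool = True
    synthetic_overrides: dict = field(default_factory=dict)
    clusters_csv: str | None = None
    admin_geojson: str | None = None
    population_raster: str | None = None
    covariate_rasters: dict[str, str] = field(default_factory=dict)
    engine_options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls(**yaml.safe_load(Path(path).read_text()))
        for p in [cfg.clusters_csv, cfg.admin_geojson, cfg.population_raster,
                  *cfg.covariate_rasters.values()]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input does not exist: {p}")
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seconds: dict[str, float]
    stage_seeds: dict[str, int]
    outputs: dict[str, str]
    version: str = "0.1.0"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def demo_config(out_dir: str = "geocci_demo", seed: int = 0) -> PipelineConfig:
    """A desk-scale demonstration run: 40×40 grid of 5 km cells, 300
    clusters, 200 posterior samples, 4 admin1 × 6 admin2 units (cluster
    density per admin1 comparable to the full-scale default)."""
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        n_posterior_samples=200,
        synthetic=True,
        synthetic_overrides={
            "n_clusters": 300,
            "n_admin1": 4,
            "n_admin2_per_admin1": 6,
        },
    )


def run_pipeline(config: PipelineConfig):
    """Execute all stages; returns (manifest, results dict).

    Results hold the in-memory artifacts (bundle, fits, stacks, tables,
    reports); files are written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t_all = time.time()
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ["simulate", "select", "fit", "predict", "validate"], ss.spawn(5)
        )
    }
    results: dict = {}

    # --- stage 1: data ----------------------------------------------------
    t0 = time.time()
    if config.synthetic:
        scfg = synthetic.SyntheticConfig(
            seed=stage_seeds["simulate"], **config.synthetic_overrides
        )
        bundle = synthetic.generate(scfg)
        bundle.write(out / "input")
        dataset, admin = bundle.dataset, bundle.admin
        grid = scfg.grid_template()
        population = bundle.field.population
        cov_rasters = bundle.field.covariates
        results["bundle"] = bundle
    else:
        for name, p in [("clusters_csv", config.clusters_csv),
                        ("admin_geojson", config.admin_geojson),
                        ("population_raster", config.population_raster)]:
            if p is None:
                raise ValueError(f"real mode requires {name}")
        dataset = SurveyDataset.from_csv(config.clusters_csv)
        admin = AdminHierarchy.from_geojson(config.admin_geojson)
        population = RasterGrid.read_ascii(config.population_raster)
        cov_rasters = {
            k: RasterGrid.read_ascii(v) for k, v in config.covariate_rasters.items()
        }
        for name, r in cov_rasters.items():
            if not r.same_geometry(population):
                raise ValueError(f"covariate raster {name!r} misaligned with population")
        grid = population.like(population.values)
    timings["data"] = time.time() - t0
    log.info("data stage done (%.1fs)", timings["data"])

    # --- stage 2: covariate selection --------------------------------------
    t0 = time.time()
    selections = {}
    matrices = {}
    from .covariates import extract_covariates

    raw = extract_covariates(cov_rasters, dataset.clusters())
    for name in INDICATORS:
        matrices[name], selections[name] = select_covariates(
            dataset, name, raw=raw
        )
        selections[name].to_json(out / f"selection_{name}.json")
        log.debug("selected %s for %s", selections[name].final_covariates, name)
    outputs.update({f"selection_{n}": f"selection_{n}.json" for n in INDICATORS})
    results["selections"] = selections
    timings["select"] = time.time() - t0
    log.info("covariate selection done (%.1fs)", timings["select"])

    # --- stage 3: fit + predict per indicator ------------------------------
    t0 = time.time()
    fits = {}
    stacks = {}
    for k, name in enumerate(INDICATORS):
        spec = ModelSpec(
            indicator=name,
            covariates=matrices[name].columns,
            priors=PriorSpec(),
            n_samples=config.n_posterior_samples,
            seed=stage_seeds["fit"] + k,
            engine=config.engine,
            engine_options=dict(config.engine_options),
        )
        fits[name] = fit_indicator(dataset, matrices[name], spec)
        stacks[name] = predict_surface(
            fits[name], grid, cov_rasters, seed=stage_seeds["predict"] + k
        )
        summ = summarize_stack(stacks[name])
        summ["mean"].write_ascii(out / f"{name}_mean.asc")
        summ["width"].write_ascii(out / f"{name}_width.asc")
        outputs[f"{name}_mean"] = f"{name}_mean.asc"
        outputs[f"{name}_width"] = f"{name}_width.asc"
        log.info("fitted and predicted %s", name)
    results["fits"] = fits
    results["stacks"] = stacks
    timings["fit_predict"] = time.time() - t0

    # --- stage 4: CCI + aggregation ----------------------------------------
    t0 = time.time()
    cci_stack = combine_posterior_stacks(stacks)
    results["cci_stack"] = cci_stack
    summ = summarize_stack(cci_stack)
    summ["mean"].write_ascii(out / "CCI_mean.asc")
    summ["width"].write_ascii(out / "CCI_width.asc")
    outputs["CCI_mean"] = "CCI_mean.asc"
    outputs["CCI_width"] = "CCI_width.asc"
    admin2 = aggregate_population_weighted(cci_stack, population, admin, level=2)
    admin1 = aggregate_population_weighted(cci_stack, population, admin, level=1)
    admin2.to_csv(out / "CCI_admin2.csv")
    admin1.to_csv(out / "CCI_admin1.csv")
    outputs["CCI_admin2"] = "CCI_admin2.csv"
    outputs["CCI_admin1"] = "CCI_admin1.csv"
    consistency = nested_consistency_check(admin2, admin1, admin)
    if not consistency.ok:
        log.warning("nested aggregation violations: %s", consistency.violations)
    results["admin2"] = admin2
    results["admin1"] = admin1
    results["consistency"] = consistency
    timings["aggregate"] = time.time() - t0

    # --- stage 5: validation ------------------------------------------------
    t0 = time.time()
    direct = direct_cci_estimate(dataset, admin, level=1)
    comparison = compare_admin(admin1.table, direct)
    comparison.table.to_csv(out / "admin1_comparison.csv", index=False)
    outputs["admin1_comparison"] = "admin1_comparison.csv"
    results["comparison"] = comparison
    cv_results = {}
    for name in config.cv_indicators:
        folds = make_folds(dataset, name, K=config.cv_folds,
                           seed=stage_seeds["validate"])
        spec = ModelSpec(
            indicator=name, covariates=matrices[name].columns,
            n_samples=max(100, config.n_posterior_samples // 4),
            seed=stage_seeds["validate"], engine=config.engine,
            engine_options=dict(config.engine_options),
        )
        cv = cross_validate(dataset, matrices[name], spec, folds)
        cv_results[name] = cv
        (out / f"cv_{name}.json").write_text(json.dumps({
            "mean_error": cv.mean_error, "mae": cv.mae,
            "correlation": cv.correlation, "n_clusters": cv.n_clusters,
        }, indent=1))
        outputs[f"cv_{name}"] = f"cv_{name}.json"
    results["cv"] = cv_results
    timings["validate"] = time.time() - t0
    timings["total"] = time.time() - t_all

    outputs = {k: v for k, v in outputs.items()}
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        stage_seconds={k: round(v, 2) for k, v in timings.items()},
        stage_seeds=stage_seeds,
        outputs={k: f"{v}:{_checksum(out / v)}" for k, v in outputs.items()},
    )
    manifest.write(out / "manifest.json")
    results["manifest"] = manifest
    return manifest, results
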