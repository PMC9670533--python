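"""Ground-truth generator: fields, population, displacement, sampling."""

import numpy as np
import pytest
from scipy.special import expit

from geocci.grid import RasterGrid
from geocci.model import SpatialEffectParams
from geocci.synthetic import (
    SyntheticConfig,
    build_true_surfaces,
    default_indicator_specs,
    displace_location,
    generate,
    sample_clusters,
    simulate_gaussian_field,
    simulate_population,
)


@pytest.fixture(scope="module")
def small_config():
    return SyntheticConfig(
        seed=5,
        region_size_km=100.0,
        cell_km=5.0,
        n_admin1=4,
        n_admin2_per_admin1=4,
        n_clusters=600,
    )


@pytest.fixture(scope="module")
def small_bundle(small_config):
    return generate(small_config)


def test_field_determinism_and_zero_variance_limit(small_grid):
    params = SpatialEffectParams(0.8, 30.0)
    f1 = simulate_gaussian_field(small_grid, params, seed=42)
    f2 = simulate_gaussian_field(small_grid, params, seed=42)
    assert np.array_equal(f1.values, f2.values)
    tiny = simulate_gaussian_field(small_grid, SpatialEffectParams(1e-8, 30.0), seed=1)
    assert np.max(np.abs(tiny.values)) < 1e-6


def test_field_rejects_invalid_params(small_grid):
    with pytest.raises(ValueError):
        simulate_gaussian_field(small_grid, SpatialEffectParams(0.0, 30.0), seed=0)
    with pytest.raises(ValueError):
        simulate_gaussian_field(small_grid, SpatialEffectParams(1.0, -5.0), seed=0)


def test_population_positive_normalized(small_grid):
    pop = simulate_population(small_grid, seed=9, total=1e6)
    assert np.all(pop.values > 0)
    assert pop.values.sum() == pytest.approx(1e6, rel=1e-6)
    again = simulate_population(small_grid, seed=9, total=1e6)
    assert np.array_equal(pop.values, again.values)


def test_true_surface_closed_forms():
    # beta = 0, omega ~ 0, intercept 0 -> p = 1/2; intercept 20 -> saturated
    cfg = SyntheticConfig(
        seed=0, region_size_km=50.0, n_admin1=1, n_admin2_per_admin1=1,
        n_clusters=10,
        beta_true={s.name: (0.0, 0.0, 0.0) for s in default_indicator_specs()},
        field_params=SpatialEffectParams(1e-9, 30.0, sigma_eps=0.0),
    )
    cfg.indicators = [
        type(s)(s.name, s.mean_trials_per_cluster, s.cluster_presence_prob, 0.0)
        for s in cfg.indicators
    ]
    field = build_true_surfaces(cfg)
    assert np.allclose(field.p_true["SBA"].values, 0.5, atol=1e-6)
    cfg.indicators = [
        type(s)(s.name, s.mean_trials_per_cluster, s.cluster_presence_prob, 20.0)
        for s in cfg.indicators
    ]
    field = build_true_surfaces(cfg)
    assert np.all(field.p_true["SBA"].values > 0.999)
    # single covariate x=2, beta 0.5, intercept 1 -> logit^{-1}(2) ~ 0.8808
    assert expit(1.0 + 0.5 * 2.0) == pytest.approx(0.88079707, abs=1e-6)


def test_national_truth_within_surface_range(small_bundle):
    field = small_bundle.field
    for name, grid in field.p_true.items():
        nat = field.national_coverage(name)
        assert grid.values.min() <= nat <= grid.values.max()


@pytest.mark.parametrize("urban,cap", [(True, 2.0), (False, 5.0)])
def test_displacement_bounded(urban, cap):
    rng = np.random.default_rng(11)
    pt = (50.0, 50.0)
    d = np.array([
        np.hypot(*(np.array(displace_location(pt, urban, rng, 100.0)) - pt))
        for _ in range(10_000)
    ])
    assert d.max() <= cap + 1e-12
    assert d.max() > 0.9 * cap  # the cap is approached


def test_displacement_disabled_identity(small_config):
    cfg = SyntheticConfig(**{**small_config.__dict__, "displacement": False,
                             "n_clusters": 50})
    b = generate(cfg)
    tl = b.dataset.true_locations.set_index("cluster_id")
    cl = b.dataset.clusters().set_index("cluster_id")
    assert np.allclose(cl["x"], tl.loc[cl.index, "x_true"])
    assert np.allclose(cl["y"], tl.loc[cl.index, "y_true"])


def test_cluster_sampling_structure(small_bundle, small_config):
    ds = small_bundle.dataset
    assert ds.n_clusters == small_config.n_clusters
    # displacement never exceeds the class maximum
    tl = ds.true_locations.set_index("cluster_id")
    cl = ds.clusters().set_index("cluster_id")
    d = np.hypot(cl["x"] - tl.loc[cl.index, "x_true"], cl["y"] - tl.loc[cl.index, "y_true"])
    cap = np.where(cl["urban"], 2.0, 5.0)
    assert np.all(d <= cap + 1e-9)
    # urban fraction matches the configured share
    assert cl["urban"].mean() == pytest.approx(small_config.urban_fraction, abs=0.01)
    # both survey rounds present and pooled
    assert set(cl["round"]) == {2018, 2019}
    # events <= trials everywhere and p == 1 impossible to violate by design
    assert (ds.table["events"] <= ds.table["trials"]).all()


def test_sparse_indicator_ordering(small_bundle):
    """Care-seeking reaches far fewer clusters than birth attendance,
    mirroring the pooled sample's 1,639 vs 6,383 ordering."""
    n_carep = len(small_bundle.dataset.for_indicator("CAREP"))
    n_sba = len(small_bundle.dataset.for_indicator("SBA"))
    assert n_carep < 0.5 * n_sba


def test_trial_means_reflect_spec():
    cfg = SyntheticConfig(
        seed=2, region_size_km=100.0, n_admin1=1, n_admin2_per_admin1=1,
        n_clusters=3000,
        indicators=[
            type(s)(s.name, 8.0 if s.name == "DPT3" else s.mean_trials_per_cluster,
                    1.0 if s.name == "DPT3" else s.cluster_presence_prob, s.intercept)
            for s in default_indicator_specs()
        ],
    )
    field = build_true_surfaces(cfg)
    ds = sample_clusters(field, cfg, seed=3)
    sub = ds.for_indicator("DPT3")
    assert len(sub) == 3000  # presence prob 1
    assert sub["trials"].mean() == pytest.approx(8.0, abs=0.15)


def test_degenerate_probability_gives_saturated_counts():
    cfg = SyntheticConfig(
        seed=4, region_size_km=50.0, n_admin1=1, n_admin2_per_admin1=1,
        n_clusters=200,
        beta_true={s.name: (0.0, 0.0, 0.0) for s in default_indicator_specs()},
        field_params=SpatialEffectParams(1e-9, 30.0, sigma_eps=0.0),
        indicators=[
            type(s)(s.name, s.mean_trials_per_cluster, s.cluster_presence_prob, 40.0)
            for s in default_indicator_specs()
        ],
    )
    field = build_true_surfaces(cfg)
    ds = sample_clusters(field, cfg, seed=5)
    assert (ds.table["events"] == ds.table["trials"]).all()


def test_bundle_roundtrip(tmp_path, small_bundle):
    small_bundle.write(tmp_path / "bundle")
    assert (tmp_path / "bundle" / "manifest.yaml").exists()
    from geocci.survey import SurveyDataset

    back = SurveyDataset.from_csv(tmp_path / "bundle" / "clusters.csv")
    assert back.n_clusters == small_bundle.dataset.n_clusters
    pop = RasterGrid.read_ascii(tmp_path / "bundle" / "population.asc")
    assert pop.same_geometry(small_bundle.field.population)


def test_config_validation():
    with pytest.raises(ValueError, match="whole number"):
        SyntheticConfig(region_size_km=101.0, cell_km=5.0)
    with pytest.raises(ValueError, match="eight"):
        SyntheticConfig(indicators=default_indicator_specs()[:-1])
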