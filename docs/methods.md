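# Methods

## Estimand and model

The pipeline maps coverage of eight RMNCH interventions and their composite
index over a region from clustered survey counts.  The unit of analysis is
the survey cluster (enumeration area); for indicator k and cluster i the
data are `(events, trials)` pairs and the model is a binomial spatial GLMM:

    Y_i ~ Binomial(N_i, p_i),
    logit p_i = x_i' β + ω(s_i) + ε_i,

with `ω` a zero-mean stationary Gaussian process and `ε ~ N(0, σ_ε²)` an
iid nugget.  The mapped quantity is the **nugget-free** surface
`logit⁻¹(x'β + ω)`: the nugget represents cluster-level sampling and
measurement noise, not a feature of place, so predictions integrate it out.
Cluster coordinates are the *reported* (randomly displaced) ones;
displacement is acknowledged through buffered covariate extraction (discs
of 2 km urban / 5 km rural radius, matching the displacement maxima), not
corrected.

### Matérn covariance and the range convention

`cov(d) = σ_ω² · 2^{1−ν}/Γ(ν) · (κd)^ν K_ν(κd)`, with smoothness fixed at
ν = 1 (the conventional choice for 2-D spatial interpolation; the data are
rarely informative about ν).  The range parameter ρ is defined as the
**practical range**: the distance at which correlation has decayed to 0.1.
κ is solved numerically from that definition per ν (κρ = ln 10 for ν = ½,
κρ ≈ 3.2143 for ν = 1).  This convention is self-consistent across the
generator, the likelihood and the tests; users porting hyperparameters from
software that uses κρ = √(8ν) (correlation ≈ 0.13–0.14 at ρ) should rescale
by ≈ 0.88 for ν = 1.

### Priors

Weakly-informative, penalised-complexity-shaped defaults, exposed in
`PriorSpec`: β ~ N(0, 10²) independently; σ_ω and σ_ε exponential with
P(σ > 1) = 0.1 (1 logit unit is a large residual effect for proportions);
ρ with the PC-type density λρ⁻² e^{−λ/ρ} and median at 10% of the data
diameter.  These regularize the weakly identified hyperparameters at
realistic survey sizes without dominating them.

## Inference engines

The fitting contract is the joint posterior of `(β, hyperparameters, field
at data locations)`; two engines satisfy it.

**laplace (default).**  The latent field is handled through the combined
residual `u = ω + ε` with covariance `Σ_ω + σ_ε² I` (exactly the marginal
model; kriging `u` with the nugget on the diagonal recovers the ε-free ω at
any target).  For fixed hyperparameters θ = (log σ_ω, log ρ, log σ_ε), a
damped Newton ascent finds the joint mode of `(β, u)` and the Gaussian
(Laplace) approximation supplies both the conditional posterior and the
marginal likelihood.  θ is optimized by Nelder–Mead; a numerical Hessian at
the mode defines a small design of 7 hyperparameter nodes (mode ± 1.2 SD
along principal axes) weighted by the Laplace marginal posterior, and the S
requested samples are drawn from the resulting Gaussian mixture.  This is a
deliberately small-scale analogue of grid-integrated nested Laplace
inference: hyperparameter uncertainty is propagated, at the cost of one
Newton solve per node.  Cost is O(n³) per likelihood evaluation; intended
for n up to a few thousand clusters.

**mcmc (oracle).**  An exact sampler used on small instances to audit the
approximation: elliptical slice sampling on the whitened latent vector
(β/σ_β, L⁻¹u jointly), alternated with an adaptive random-walk Metropolis
step on log θ (non-centered, so the field re-scales coherently when θ
moves).  Default 6,000 iterations with half burn-in.  Agreement criterion
used in the tests: posterior means of β within 0.5 posterior SD.

**Prediction** at grid cells or held-out clusters is conditional simulation:
per posterior sample, ω at the targets is drawn from its Gaussian
distribution given the sampled `u` (mean `C K⁻¹ u`, covariance
`Σ_tt − C K⁻¹ C'`), added to `x'β`, and inverse-logit transformed.
Factorizations are shared across samples with equal θ (the 7 nodes), which
keeps surface prediction cheap.  Degenerate inputs: indicators with all-zero
or all-full events are rejected; covariance factorizations escalate a
diagonal jitter (starting at 10⁻⁸ of the mean diagonal) before failing.

## Covariate preparation

Buffer extraction averages raster cells whose centers fall in the 2/5 km
disc; with 5 km cells the disc often contains no center and the containing
cell's value is used.  Nodata cells are excluded; an all-nodata buffer falls
back to the nearest valid cell.

Fractional polynomials use the conventional power set
{−2, −1, −0.5, 0 (= log), 0.5, 1, 2, 3}, first and second order, with
repeated powers (p, p) → (x^p, x^p ln x).  Covariates are shifted positive
(by −min + 1% of range, computed over *all* clusters) before transformation
and each transformed column is standardized; at prediction time raster
values below the training support are clamped to half the training minimum
— the transform domain must stay positive and extreme extrapolation of FP
curves is meaningless anyway.  The best transform is chosen by binomial
deviance under Royston-style closed testing (FP2 must beat FP1 at χ²₂ 0.05,
FP1 must beat linear at χ²₁ 0.05); a covariate that cannot beat the
intercept-only model is flagged weak and left linear.  This keeps the
selection calibrated: a pure-noise covariate survives to the final model at
≈ the nominal 5% rate.

Collinearity pruning removes, among all pairs with Pearson |r| > 0.8, the
column with the smaller single-covariate |Wald z| (the operational meaning
given to "strongest association with the outcome"), iterating until no
pair exceeds the threshold.  Backward elimination then drops the largest
Wald p while it exceeds 0.05, allowing the empty model.  Selection fits are
unweighted cluster-level binomial GLMs — spatial correlation is deferred to
the geostatistical model.

## Synthetic study generator

The generator emulates the pooled two-round survey feeding the pipeline,
with full ground truth.  Defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| clusters | 6,508 (2 × 3,254, pooled rounds) | pooled survey size |
| cell size | 5 km | mapping resolution |
| region | 200 km square (40 × 40 cells) | scaled extent, see below |
| admin | 25 admin1 × 8 admin2 | 25 departments / ≈196 provinces |
| urban fraction | 0.6 | majority-urban cluster frame |
| σ_ω, ρ, σ_ε | 0.5, 50 km, 0.3 | moderate residual field, range ≈ ¼ region |
| population | 31 M, exponentiated smooth field | right-skewed settlement |
| per-indicator trials, presence, intercept | from the pooled sample description | e.g. SBA: 6,383/6,508 clusters, 3.84 trials/cluster, logit(0.946); CAREP: 25% presence, 1.19 trials |

Three standardized smooth covariate surfaces (travel time, women's
education, improved sanitation; ranges 80/60/100 km) drive coverage with
per-indicator coefficients — strong for the pregnancy indicators, weak for
care-seeking — reproducing the qualitative predictability ordering of real
surveys.  Trials are zero-truncated Poisson thinned by a presence
probability; events are binomial at the cell's true p with the nugget added
per cluster on the logit scale (the stored truth is the nugget-free p, the
models' prediction target).  Displacement is uniform in angle and in radius
on [0, 2] km (urban) / [0, 5] km (rural), clipped to the region; the rare
long-distance rural displacement some surveys apply to 1% of clusters is
not emulated.  Urban status goes to clusters in the most populous cells.
Admin units are a rectangular two-level partition; real polygons enter
through the same GeoJSON interface.

The spatial extent is deliberately scaled: a continental-scale grid at 5 km
would dominate run time without changing any contract being tested.  The
demonstration configuration (300 clusters, 4 × 6 admin units, S = 200)
keeps ~75 clusters per admin1 — the same order as the real survey's ~260
per department — so the direct-estimate comparator remains estimable.
What the synthetic design does *not* contain: survey weights and two-stage
household sampling (clusters are self-weighting here), measurement error in
covariates, coastline/holes in the region, and temporal drift between the
pooled rounds.  Passing tests therefore validate the estimation machinery,
not robustness to those real-data features.

## Aggregation and validation

CCI combination happens at cell level, per posterior sample; aggregation to
admin units is the population-weighted mean of each sample (cell-center
containment assigns cells to units), and summaries (mean, median, 2.5/97.5
percentiles with linear interpolation, CrI width) are taken afterwards —
aggregating before summarizing is required for coherent admin-level
intervals.  A consistency check verifies per sample that admin1 estimates
equal the population-weighted means of their admin2 children (tolerance
1e-10).

Cross-validation partitions clusters into K = 5 random folds balanced over
clusters with positive trials, enforcing the 50-cluster floor per fold and
raising with the deficit when infeasible.  Folds are random rather than
spatially blocked (a blocked strategy can be plugged in through the same
interface).  Held-out prediction uses the posterior mean of p; metrics are
mean error, MAE and Pearson r, pooled over held-out clusters.  Direct admin
estimates pool cluster counts unweighted (self-weighting synthetic design);
the admin1 CCI comparator is the CCI of the eight pooled proportions.

## Numerical and design choices

- Internal probability scale is [0, 1]; presentation multiplies by 100.
  The CCI weights are exact rationals (sum exactly 1), so constant vectors
  are fixed points to machine precision.
- Missing CCI components are an error — no silent reweighting of the index.
- Per-stage seeds are spawned from the global seed via `SeedSequence`, so
  adding stages never shifts earlier random streams; identical configs
  reproduce identical output checksums in deterministic stages.
- Percentile rule: linear interpolation between order statistics; summaries
  warn when computed from fewer than 40 samples.
- Planar km coordinates throughout; real lon/lat inputs must be projected
  before use.

## Known limitations

- Dense-matrix inference: O(n³) in clusters and grid cells; fine at survey
  scale (≤ a few thousand), not at continental raster scale.  A sparse
  (SPDE/GMRF mesh) backend would be the natural extension.
- The Laplace engine understates hyperparameter uncertainty relative to
  full MCMC when n is small and θ is weakly identified; β inference is
  audited against the MCMC oracle instead.
- Direct estimates ignore survey design weights; with real microdata the
  weighted comparator should be supplied externally.
- The national CCI computed from eight national coverage percentages is not
  identical to an individual-level national CCI (different micro-weighting);
  both estimators are exposed, neither is claimed to equal the other.
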