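"""Bayesian binomial geostatistical model for coverage surfaces.

One model per indicator.  With ``Y(s_i)`` events out of ``N(s_i)`` trials at
cluster location ``s_i``:

    Y(s_i) ~ Binomial(N(s_i), p(s_i))
    logit p(s_i) = x(s_i)' beta + omega(s_i) + eps(s_i)

``omega`` is a zero-mean stationary Gaussian process with Matérn covariance
capturing residual spatial correlation, and ``eps`` is an iid Gaussian nugget
absorbing non-spatial cluster-level variation.  The model is fit in a
Bayesian framework; the contract is the joint posterior of
``(beta, hyperparameters, omega at data locations)``, not a particular
algorithm.  Two engines satisfy it:

``laplace`` (default)
    A Gaussian (Laplace/GMRF) approximation to the latent field combined
    with numerical integration over the three covariance hyperparameters on
    a small design of points around the posterior mode — fast enough for
    pipeline runs and cross-validation.
``mcmc``
    An exact sampler (elliptical slice sampling for the whitened latent
    field and regression effects, Metropolis for the hyperparameters), used
    as the oracle on small instances.

The Matérn range parameter follows the *practical range* convention: it is
the distance at which the correlation has decayed to 0.1.

Predictions target the epsilon-free surface ``logit^{-1}(x'beta + omega)``:
the nugget is cluster sampling noise, not part of the mapped surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, optimize, special
from scipy.spatial.distance import cdist
from scipy.special import expit, gammaln, kv, log_expit

__all__ = [
    "SpatialEffectParams",
    "PriorSpec",
    "ModelSpec",
    "IndicatorFit",
    "matern_covariance",
    "matern_kappa",
    "fit_indicator",
    "fit_binomial_gp",
    "predict_at_points",
    "predict_surface",
    "DegenerateDataError",
    "NonConvergenceError",
]

#: Correlation at the practical range.
RANGE_CORRELATION = 0.1


class DegenerateDataError(ValueError):
    """All-zero or all-full event counts: the likelihood cannot identify p."""


class NonConvergenceError(RuntimeError):
    """Inference failed to converge; carries diagnostics."""


@dataclass
class SpatialEffectParams:
    """Hyperparameters of the spatial (omega) and nugget (eps) effects.

    sigma_omega : marginal SD of the spatial field on the logit scale.
    range_rho   : practical range in km — the distance at which the Matérn
                  correlation equals 0.1.
    nu          : Matérn smoothness (default 1, the conventional choice for
                  2-D spatial interpolation).
    sigma_eps   : SD of the iid nugget on the logit scale.
    """

    sigma_omega: float
    range_rho: float
    nu: float = 1.0
    sigma_eps: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_omega <= 0:
            raise ValueError("sigma_omega must be > 0")
        if self.range_rho <= 0:
            raise ValueError("range_rho must be > 0")
        if self.nu <= 0:
            raise ValueError("nu must be > 0")
        if self.sigma_eps < 0:
            raise ValueError("sigma_eps must be >= 0")


@lru_cache(maxsize=32)
def _kappa_times_range(nu: float) -> float:
    """Solve for kappa*rho such that the Matérn correlation at rho is 0.1."""

    def corr(x: float) -> float:
        return (2.0 ** (1.0 - nu) / np.exp(gammaln(nu))) * x**nu * kv(nu, x)

    return optimize.brentq(lambda x: corr(x) - RANGE_CORRELATION, 1e-8, 50.0)


def matern_kappa(nu: float, range_rho: float) -> float:
    """Matérn scale parameter kappa for a given practical range."""
    if range_rho <= 0:
        raise ValueError("range_rho must be > 0")
    return _kappa_times_range(float(nu)) / range_rho


def matern_covariance(d, params: SpatialEffectParams):
    """Matérn covariance sigma^2 * 2^(1-nu)/Gamma(nu) * (kd)^nu * K_nu(kd).

    ``d`` is distance in km (scalar or array, >= 0); returns sigma_omega^2 at
    d = 0.  The nugget is *not* included.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    nu = float(params.nu)
    kappa = matern_kappa(nu, params.range_rho)
    x = kappa * d
    with np.errstate(invalid="ignore"):
        c = (2.0 ** (1.0 - nu) / np.exp(gammaln(nu))) * x**nu * kv(nu, x)
    c = np.where(d == 0, 1.0, c)
    out = params.sigma_omega**2 * c
    if out.ndim == 0:
        return float(out)
    return out


def _matern_corr_matrix(D: np.ndarray, range_rho: float, nu: float) -> np.ndarray:
    kappa = _kappa_times_range(float(nu)) / range_rho
    x = kappa * D
    with np.errstate(invalid="ignore"):
        c = (2.0 ** (1.0 - nu) / np.exp(gammaln(nu))) * x**nu * kv(nu, x)
    return np.where(D == 0, 1.0, c)


@dataclass
class PriorSpec:
    """Penalised-complexity-shaped default priors.

    beta: independent N(0, beta_sd^2).  sigma_omega and sigma_eps:
    exponential with P(sigma > sigma_u) = sigma_tail_prob.  range_rho:
    inverse-type PC prior with P(range < range_median) = 0.5; by default the
    median is set to 10% of the region diameter at fit time.
    """

    beta_sd: float = 10.0
    range_median: float | None = None
    sigma_u: float = 1.0
    sigma_tail_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.beta_sd <= 0 or self.sigma_u <= 0:
            raise ValueError("prior scales must be positive")
        if not 0 < self.sigma_tail_prob < 1:
            raise ValueError("sigma_tail_prob must be in (0,1)")
        if self.range_median is not None and self.range_median <= 0:
            raise ValueError("range_median must be positive")

    def resolved(self, coords: np.ndarray) -> "PriorSpec":
        if self.range_median is not None:
            return self
        lo = coords.min(axis=0)
        hi = coords.max(axis=0)
        diam = float(np.hypot(*(hi - lo)))
        return PriorSpec(self.beta_sd, max(0.1 * diam, 1e-3), self.sigma_u, self.sigma_tail_prob)

    # log-densities on the log scale (Jacobian included)
    def log_prior_theta(self, ltheta: np.ndarray) -> float:
        lam_s = -np.log(self.sigma_tail_prob) / self.sigma_u
        s_om, rho, s_eps = np.exp(ltheta)
        lp = np.log(lam_s) - lam_s * s_om + ltheta[0]
        lp += np.log(lam_s) - lam_s * s_eps + ltheta[2]
        lam_r = np.log(2.0) * self.range_median
        lp += np.log(lam_r) - 2.0 * np.log(rho) - lam_r / rho + ltheta[1]
        return float(lp)


@dataclass
class ModelSpec:
    """What to fit: indicator, covariate columns, priors, engine settings."""

    indicator: str
    covariates: Sequence[str] = ()
    priors: PriorSpec = field(default_factory=PriorSpec)
    n_samples: int = 1000
    seed: int = 0
    engine: str = "laplace"
    nu: float = 1.0
    engine_options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("need at least 2 posterior samples")
        if self.engine not in {"laplace", "mcmc"}:
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass
class IndicatorFit:
    """Joint posterior samples for one indicator's geostatistical model.

    ``u_samples`` are draws of the *combined* residual u = omega + eps at the
    data locations; prediction recovers the eps-free omega at any target
    location by kriging u with the nugget on the diagonal, which integrates
    the nugget out exactly.
    """

    indicator: str
    engine: str
    seed: int
    nu: float
    design_columns: list[str]
    X: np.ndarray                 # (n, p) design incl. intercept
    y: np.ndarray                 # (n,) events
    n_trials: np.ndarray          # (n,) trials
    coords: np.ndarray            # (n, 2) reported cluster locations, km
    beta_samples: np.ndarray      # (S, p)
    u_samples: np.ndarray         # (S, n)
    theta_samples: np.ndarray     # (S, 3): sigma_omega, range_rho, sigma_eps
    prior: PriorSpec
    diagnostics: dict = field(default_factory=dict)
    transforms: list = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.beta_samples.shape[0]

    def posterior_summary(self) -> dict:
        """Posterior means, SDs and 95% credible intervals."""
        out = {}
        for name, arr in [("beta", self.beta_samples), ("theta", self.theta_samples)]:
            labels = (
                self.design_columns
                if name == "beta"
                else ["sigma_omega", "range_rho", "sigma_eps"]
            )
            for j, lab in enumerate(labels):
                col = arr[:, j]
                out[lab] = {
                    "mean": float(col.mean()),
                    "sd": float(col.std(ddof=1)),
                    "q025": float(np.percentile(col, 2.5)),
                    "q975": float(np.percentile(col, 97.5)),
                }
        return out

    def in_sample_eta(self) -> np.ndarray:
        """(S, n) posterior samples of the linear predictor at data points."""
        return self.beta_samples @ self.X.T + self.u_samples

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            X=self.X, y=self.y, n_trials=self.n_trials, coords=self.coords,
            beta_samples=self.beta_samples, u_samples=self.u_samples,
            theta_samples=self.theta_samples,
        )
        meta = {
            "indicator": self.indicator,
            "engine": self.engine,
            "seed": self.seed,
            "nu": self.nu,
            "design_columns": self.design_columns,
            "prior": asdict(self.prior),
            "diagnostics": {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.diagnostics.items()
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "IndicatorFit":
        path = Path(path)
        arrs = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            indicator=meta["indicator"], engine=meta["engine"], seed=meta["seed"],
            nu=meta["nu"], design_columns=meta["design_columns"],
            X=arrs["X"], y=arrs["y"], n_trials=arrs["n_trials"], coords=arrs["coords"],
            beta_samples=arrs["beta_samples"], u_samples=arrs["u_samples"],
            theta_samples=arrs["theta_samples"],
            prior=PriorSpec(**meta["prior"]), diagnostics=meta["diagnostics"],
        )


# ---------------------------------------------------------------------------
# likelihood helpers
# ---------------------------------------------------------------------------

def _binom_loglik(eta: np.ndarray, y: np.ndarray, n: np.ndarray) -> float:
    return float(np.sum(y * log_expit(eta) + (n - y) * log_expit(-eta)))


def _chol_with_jitter(M: np.ndarray, base: float = 1e-8) -> np.ndarray:
    """Lower Cholesky factor, escalating diagonal jitter on failure."""
    scale = float(abs(np.mean(np.diag(M)))) or 1.0
    for k in range(8):
        try:
            return linalg.cholesky(M + base * 10**k * scale * np.eye(M.shape[0]), lower=True)
        except linalg.LinAlgError:
            continue
    raise NonConvergenceError("covariance matrix is numerically indefinite")


# ---------------------------------------------------------------------------
# Laplace / GMRF engine
# ---------------------------------------------------------------------------

class _LaplaceCore:
    """Gaussian approximation over (beta, u) for fixed hyperparameters."""

    def __init__(self, y, n, X, D, nu, prior: PriorSpec):
        self.y, self.n, self.X, self.D, self.nu, self.prior = y, n, X, D, nu, prior
        self.p = X.shape[1]
        self.N = X.shape[0]
        self._warm: np.ndarray | None = None

    def evaluate(self, ltheta: np.ndarray, keep: bool = False):
        """Laplace log marginal posterior of theta (up to a constant).

        Returns (logpost, mode, chol_H) with the latter two present only when
        ``keep`` is True.
        """
        s_om, rho, s_eps = np.exp(ltheta)
        Sigma = s_om**2 * _matern_corr_matrix(self.D, rho, self.nu)
        jit = 1e-8 * (s_om**2 + s_eps**2 + 1e-12)
        Sigma[np.diag_indices_from(Sigma)] += s_eps**2 + jit
        Lu = _chol_with_jitter(Sigma)
        logdet_Sigma = 2.0 * float(np.sum(np.log(np.diag(Lu))))
        Qu = linalg.cho_solve((Lu, True), np.eye(self.N))

        p, N = self.p, self.N
        bsd2 = self.prior.beta_sd**2
        v = self._warm if self._warm is not None else np.zeros(p + N)

        def objective(v):
            beta, u = v[:p], v[p:]
            eta = self.X @ beta + u
            return (
                _binom_loglik(eta, self.y, self.n)
                - 0.5 * float(beta @ beta) / bsd2
                - 0.5 * float(u @ (Qu @ u))
            )

        obj = objective(v)
        H_chol = None
        for it in range(100):
            beta, u = v[:p], v[p:]
            eta = self.X @ beta + u
            mu = expit(eta)
            w = np.clip(self.n * mu * (1 - mu), 1e-12, None)
            r = self.y - self.n * mu
            grad = np.concatenate([self.X.T @ r - beta / bsd2, r - Qu @ u])
            H = np.empty((p + N, p + N))
            H[:p, :p] = (self.X.T * w) @ self.X + np.eye(p) / bsd2
            H[:p, p:] = self.X.T * w
            H[p:, :p] = H[:p, p:].T
            H[p:, p:] = Qu + np.diag(w)
            H_chol = _chol_with_jitter(H, base=1e-12)
            step = linalg.cho_solve((H_chol, True), grad)
            # damped Newton
            t = 1.0
            for _ in range(40):
                v_new = v + t * step
                obj_new = objective(v_new)
                if obj_new >= obj - 1e-12:
                    break
                t *= 0.5
            moved = float(np.max(np.abs(t * step)))
            v, obj = v_new, obj_new
            if moved < 1e-8 or float(np.max(np.abs(grad))) < 1e-6 * max(1.0, np.max(self.n)):
                break
        self._warm = v.copy()

        logdet_H = 2.0 * float(np.sum(np.log(np.diag(H_chol))))
        logdet_Q = -logdet_Sigma - 2 * p * np.log(self.prior.beta_sd)
        logpost = obj + 0.5 * logdet_Q - 0.5 * logdet_H + self.prior.log_prior_theta(ltheta)
        if keep:
            return logpost, v, H_chol
        return logpost, None, None


def _fit_laplace(y, n, X, coords, spec: ModelSpec, prior: PriorSpec, rng):
    D = cdist(coords, coords)
    core = _LaplaceCore(y, n, X, D, spec.nu, prior)
    opts = spec.engine_options
    start = np.log(
        np.asarray(opts.get("theta_start", [0.5, prior.range_median, 0.3]), dtype=float)
    )

    nfev = [0]

    def negpost(lt):
        nfev[0] += 1
        return -core.evaluate(lt)[0]

    res = optimize.minimize(
        negpost, start, method="Nelder-Mead",
        options={"xatol": 0.02, "fatol": 0.05, "maxfev": opts.get("maxfev", 200)},
    )
    mode = res.x

    # numerical Hessian of the log posterior at the mode
    h = 0.2
    f0 = -res.fun
    dim = 3
    Hess = np.zeros((dim, dim))
    fp = np.zeros(dim)
    fm = np.zeros(dim)
    for i in range(dim):
        e = np.zeros(dim); e[i] = h
        fp[i] = core.evaluate(mode + e)[0]
        fm[i] = core.evaluate(mode - e)[0]
        Hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / h**2
    for i in range(dim):
        for j in range(i + 1, dim):
            ei = np.zeros(dim); ei[i] = h
            ej = np.zeros(dim); ej[j] = h
            fpp = core.evaluate(mode + ei + ej)[0]
            fmm = core.evaluate(mode - ei - ej)[0]
            Hess[i, j] = Hess[j, i] = (fpp - 2 * f0 + fmm) / (2 * h**2) - (
                Hess[i, i] + Hess[j, j]
            ) / 2.0

    neg_H = -(Hess + Hess.T) / 2.0
    evals, evecs = linalg.eigh(neg_H)
    evals = np.clip(evals, 1e-2, None)
    sds = 1.0 / np.sqrt(evals)

    # hyperparameter design: mode plus +-delta steps along principal axes
    delta = 1.2
    nodes = [mode]
    for i in range(dim):
        nodes.append(mode + delta * sds[i] * evecs[:, i])
        nodes.append(mode - delta * sds[i] * evecs[:, i])

    node_info = []
    logposts = []
    for nd in nodes:
        lp, v_hat, H_chol = core.evaluate(nd, keep=True)
        node_info.append((nd, v_hat, H_chol))
        logposts.append(lp)
    logposts = np.asarray(logposts)
    w = np.exp(logposts - logposts.max())
    w /= w.sum()

    S = spec.n_samples
    counts = rng.multinomial(S, w)
    p = X.shape[1]
    beta_s = np.empty((S, p))
    u_s = np.empty((S, len(y)))
    theta_s = np.empty((S, 3))
    pos = 0
    for (nd, v_hat, H_chol), c in zip(node_info, counts):
        if c == 0:
            continue
        z = rng.standard_normal((p + len(y), c))
        draw = v_hat[:, None] + linalg.solve_triangular(H_chol.T, z, lower=False)
        beta_s[pos : pos + c] = draw[:p].T
        u_s[pos : pos + c] = draw[p:].T
        theta_s[pos : pos + c] = np.exp(nd)
        pos += c
    perm = rng.permutation(S)
    diagnostics = {
        "theta_mode": np.exp(mode).tolist(),
        "opt_nfev": nfev[0],
        "opt_converged": bool(res.success or res.fun < np.inf),
        "node_weights": w.tolist(),
    }
    return beta_s[perm], u_s[perm], theta_s[perm], diagnostics


# ---------------------------------------------------------------------------
# MCMC oracle engine
# ---------------------------------------------------------------------------

def _fit_mcmc(y, n, X, coords, spec: ModelSpec, prior: PriorSpec, rng):
    """Elliptical slice sampling for whitened (beta, field); Metropolis for
    the hyperparameters.  Exact (asymptotically) but slower than Laplace."""
    opts = spec.engine_options
    n_iter = int(opts.get("n_iter", 6000))
    burn = int(opts.get("burn", n_iter // 2))
    D = cdist(coords, coords)
    N, p = X.shape
    bsd = prior.beta_sd

    def chol_for(ltheta):
        s_om, rho, s_eps = np.exp(ltheta)
        Sigma = s_om**2 * _matern_corr_matrix(D, rho, spec.nu)
        Sigma[np.diag_indices_from(Sigma)] += s_eps**2 + 1e-8 * (s_om**2 + s_eps**2 + 1e-12)
        return _chol_with_jitter(Sigma)

    ltheta = np.log(np.asarray(opts.get("theta_start", [0.5, prior.range_median, 0.3])))
    L = chol_for(ltheta)
    b = np.zeros(p)
    z = np.zeros(N)

    def loglik(b, z, L):
        eta = X @ (bsd * b) + L @ z
        return _binom_loglik(eta, y, n)

    ll = loglik(b, z, L)
    prop_sd = 0.25
    n_acc = 0
    n_prop = 0
    keep_every = max(1, (n_iter - burn) // spec.n_samples)
    kept_b, kept_u, kept_theta = [], [], []

    for it in range(n_iter):
        # --- elliptical slice sample the whitened latent vector (b, z)
        nu_b = rng.standard_normal(p)
        nu_z = rng.standard_normal(N)
        log_u = np.log(rng.uniform())
        thresh = ll + log_u
        phi = rng.uniform(0, 2 * np.pi)
        lo, hi = phi - 2 * np.pi, phi
        while True:
            b_new = b * np.cos(phi) + nu_b * np.sin(phi)
            z_new = z * np.cos(phi) + nu_z * np.sin(phi)
            ll_new = loglik(b_new, z_new, L)
            if ll_new > thresh:
                b, z, ll = b_new, z_new, ll_new
                break
            if phi > 0:
                hi = phi
            else:
                lo = phi
            phi = rng.uniform(lo, hi)

        # --- Metropolis on log hyperparameters (whitened field fixed)
        lt_prop = ltheta + prop_sd * rng.standard_normal(3)
        L_prop = chol_for(lt_prop)
        ll_prop = loglik(b, z, L_prop)
        log_alpha = (
            ll_prop + prior.log_prior_theta(lt_prop) - ll - prior.log_prior_theta(ltheta)
        )
        n_prop += 1
        if np.log(rng.uniform()) < log_alpha:
            ltheta, L, ll = lt_prop, L_prop, ll_prop
            n_acc += 1
        if it < burn and (it + 1) % 50 == 0:
            rate = n_acc / max(1, n_prop)
            prop_sd = float(np.clip(prop_sd * np.exp(rate - 0.3), 0.01, 2.0))
            n_acc = n_prop = 0

        if it >= burn and (it - burn) % keep_every == 0 and len(kept_b) < spec.n_samples:
            kept_b.append(bsd * b.copy())
            kept_u.append(L @ z)
            kept_theta.append(np.exp(ltheta))

    while len(kept_b) < spec.n_samples:  # top up if thinning undershot
        kept_b.append(kept_b[-1])
        kept_u.append(kept_u[-1])
        kept_theta.append(kept_theta[-1])

    diagnostics = {
        "n_iter": n_iter,
        "burn": burn,
        "final_proposal_sd": prop_sd,
        "theta_last": np.exp(ltheta).tolist(),
    }
    return (
        np.asarray(kept_b),
        np.asarray(kept_u),
        np.asarray(kept_theta),
        diagnostics,
    )


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit_binomial_gp(
    y,
    n_trials,
    X,
    coords,
    spec: ModelSpec,
    design_columns: Sequence[str] | None = None,
    transforms: Sequence | None = None,
) -> IndicatorFit:
    """Fit the binomial geostatistical model to prepared arrays.

    ``X`` must already include the intercept column.  Rows with zero trials
    must be removed by the caller.
    """
    y = np.asarray(y, dtype=float)
    n_trials = np.asarray(n_trials, dtype=float)
    X = np.asarray(X, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if np.any(n_trials <= 0):
        raise ValueError("all rows must have trials > 0")
    if y.sum() == 0 or (n_trials - y).sum() == 0:
        raise DegenerateDataError(
            f"indicator {spec.indicator!r}: all-zero or all-full events"
        )
    prior = spec.priors.resolved(coords)
    rng = np.random.default_rng(spec.seed)
    if spec.engine == "laplace":
        beta_s, u_s, theta_s, diag = _fit_laplace(y, n_trials, X, coords, spec, prior, rng)
    else:
        beta_s, u_s, theta_s, diag = _fit_mcmc(y, n_trials, X, coords, spec, prior, rng)
    cols = list(design_columns) if design_columns is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    return IndicatorFit(
        indicator=spec.indicator, engine=spec.engine, seed=spec.seed, nu=spec.nu,
        design_columns=cols, X=X, y=y, n_trials=n_trials, coords=coords,
        beta_samples=beta_s, u_samples=u_s, theta_samples=theta_s,
        prior=prior, diagnostics=diag, transforms=list(transforms or []),
    )


def fit_indicator(dataset, covariates, spec: ModelSpec) -> IndicatorFit:
    """Fit one indicator's model from a survey dataset and covariate matrix.

    Uses reported (displaced) coordinates as the cluster locations, as in
    standard practice: displacement is acknowledged through buffered
    covariate extraction, not corrected.
    """
    sub = dataset.for_indicator(spec.indicator)
    if len(sub) < 50:
        raise ValueError(
            f"indicator {spec.indicator!r}: only {len(sub)} clusters with trials > 0 "
            "(need >= 50)"
        )
    ids = sub["cluster_id"].to_numpy()
    cov = covariates.rows_for(ids)
    cols = list(spec.covariates) if spec.covariates else list(cov.columns)
    missing = [c for c in cols if c not in cov.columns]
    if missing:
        raise KeyError(f"covariate columns not in matrix: {missing}")
    X = np.column_stack([np.ones(len(sub))] + [cov[c].to_numpy() for c in cols])
    names = ["intercept"] + cols
    coords = sub[["x", "y"]].to_numpy()
    tr = [t for t in getattr(covariates, "transforms", []) if t.name in cols]
    return fit_binomial_gp(
        sub["events"], sub["trials"], X, coords, spec,
        design_columns=names, transforms=tr,
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def predict_at_points(
    fit: IndicatorFit,
    X_new: np.ndarray,
    coords_new: np.ndarray,
    seed: int | None = None,
    conditional_draws: bool = True,
) -> np.ndarray:
    """(S, m) posterior predictive samples of the eps-free probability.

    For each posterior sample, the spatial field at the target locations is
    drawn from its Gaussian distribution conditional on the sampled combined
    residual at the data locations (kriging with the nugget on the diagonal),
    then passed through the inverse logit with the sampled fixed effects.
    With ``conditional_draws=False`` only the conditional mean of the field
    is used (no simulation noise) — useful for point prediction.
    """
    X_new = np.asarray(X_new, dtype=float)
    coords_new = np.atleast_2d(np.asarray(coords_new, dtype=float))
    if X_new.shape[1] != len(fit.design_columns):
        raise ValueError("design width mismatch with fit")
    rng = np.random.default_rng(fit.seed + 1 if seed is None else seed)
    S = fit.n_samples
    m = coords_new.shape[0]
    out = np.empty((S, m))

    theta_round = np.round(fit.theta_samples, 10)
    uniq, inverse = np.unique(theta_round, axis=0, return_inverse=True)
    D_oo = cdist(fit.coords, fit.coords)
    D_no = cdist(coords_new, fit.coords)
    D_nn = cdist(coords_new, coords_new) if conditional_draws else None

    for g, th in enumerate(uniq):
        s_om, rho, s_eps = th
        params = SpatialEffectParams(s_om, rho, fit.nu, s_eps)
        idx = np.flatnonzero(inverse == g)
        K = s_om**2 * _matern_corr_matrix(D_oo, rho, fit.nu)
        K[np.diag_indices_from(K)] += s_eps**2 + 1e-8 * (s_om**2 + s_eps**2 + 1e-12)
        LK = _chol_with_jitter(K)
        C = s_om**2 * _matern_corr_matrix(D_no, rho, fit.nu)
        A = linalg.cho_solve((LK, True), C.T).T      # (m, n)
        mean_field = fit.u_samples[idx] @ A.T        # (k, m)
        if conditional_draws:
            G = s_om**2 * _matern_corr_matrix(D_nn, rho, fit.nu)
            cond = G - A @ C.T
            cond = (cond + cond.T) / 2.0
            Lc = _chol_with_jitter(cond, base=1e-10)
            noise = (Lc @ rng.standard_normal((m, len(idx)))).T
        else:
            noise = 0.0
        eta = fit.beta_samples[idx] @ X_new.T + mean_field + noise
        out[idx] = expit(eta)
    return out


def predict_surface(
    fit: IndicatorFit,
    grid,
    covariate_rasters: Mapping[str, "np.ndarray"],
    seed: int | None = None,
):
    """Posterior predictive stack of the probability surface on a grid.

    ``covariate_rasters`` maps *source* covariate names to RasterGrids
    aligned with ``grid``; the fit's stored column transforms turn them into
    the design matrix.  Returns a :class:`~geocci.grid.PosteriorSampleStack`.
    """
    from .grid import PosteriorSampleStack  # local import to avoid cycle

    centers = grid.cell_centers()
    cols = [np.ones(len(centers))]
    for name, t in zip(fit.design_columns[1:], fit.transforms):
        if t.source not in covariate_rasters:
            raise KeyError(f"covariate raster {t.source!r} missing for prediction")
        rast = covariate_rasters[t.source]
        if not rast.same_geometry(grid):
            raise ValueError(f"raster {t.source!r} not aligned with prediction grid")
        cols.append(t.apply(rast.values.ravel()))
    if len(cols) != len(fit.design_columns):
        raise ValueError(
            "fit has no stored transforms for its covariates; "
            "use predict_at_points with an explicit design matrix"
        )
    X_new = np.column_stack(cols)
    samples = predict_at_points(fit, X_new, centers, seed=seed)
    return PosteriorSampleStack(samples, grid.like(grid.values), label=fit.indicator)
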