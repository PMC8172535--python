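"""Bayesian hierarchical severity regression with sex-specific atom effects.

The severity model explains (lesion-volume-corrected) NIHSS from the ten
atom scores with group-specific coefficients, plus a shared covariate
block (age, age^2, sex, four comorbidities, log WMH volume):

    hyper_sigma_beta ~ HalfCauchy(5)
    sigma_beta_g     ~ HalfCauchy(hyper_sigma_beta)
    hyper_mu_beta    ~ Normal(0, 10)
    mu_beta_g        ~ Normal(hyper_mu_beta, 10)
    alpha            ~ Normal(0, 1)
    beta_{k,g}       ~ Normal(mu_beta_g, sigma_beta_g)
    beta_age, beta_age2            ~ Normal(0, 10)
    beta_sex, comorbidity and WMHv ~ Normal(0, 1)
    eps              ~ HalfCauchy(20)
    outcome_i ~ Normal(alpha + sum_k beta_{k, g(i)} * score_ik
                       + covariates_i . beta_cov, eps)

Groups g are {all} for the pooled model and {male, female} for the
sex-hierarchical one; the two-level stratified variant inserts a
stratum level between the global hyperpriors and the sex-within-stratum
coefficients.

Posteriors are drawn with an affine-invariant ensemble MCMC sampler
(emcee) on a non-centered, log-transformed parameterization: group
coefficients are sampled as standardized offsets from their group means,
and all half-Cauchy scale parameters on the log scale (with the Jacobian
in the target density), which removes the funnel geometry that otherwise
stalls random-walk samplers in hierarchical models.  Walkers are
initialized in a small ball around the least-squares solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import arviz as az
import emcee
import numpy as np
import pandas as pd

from .design import ModelInput

__all__ = [
    "ModelSpec",
    "PosteriorSamples",
    "PosteriorSummary",
    "fit_hierarchical_model",
    "fit_stratified_model",
    "hpdi",
    "summarize_posterior",
    "difference_distribution",
    "sex_difference_table",
]

_LOG_2PI = np.log(2.0 * np.pi)
_COVARIATE_NAMES = ("beta_age", "beta_age_sq", "beta_sex",
                    "beta_hypertension", "beta_diabetes", "beta_afib",
                    "beta_cad", "beta_wmhv")


@dataclass
class ModelSpec:
    """Sampler and prior configuration for the severity model."""

    hierarchy: str = "by_sex"  # pooled | by_sex | stratified_by_sex
    hyper_sigma_scale: float = 5.0
    sigma_likelihood_scale: float = 20.0
    mu_hyper_sd: float = 10.0
    atom_prior_via_hierarchy: bool = True
    covariate_prior_sds: dict = field(default_factory=lambda: {
        "age": 10.0, "age_sq": 10.0, "sex": 1.0, "comorbidities": 1.0,
        "wmhv": 1.0})
    intercept_prior_sd: float = 1.0
    draws: int = 5000
    warmup: int = 1500
    chains: int = 2
    seed: int = 0
    thin: int = 8
    n_walkers: int | None = None

    def validate(self) -> None:
        if self.hierarchy not in ("pooled", "by_sex", "stratified_by_sex"):
            raise ValueError(f"unknown hierarchy '{self.hierarchy}'")
        for name in ("hyper_sigma_scale", "sigma_likelihood_scale",
                     "mu_hyper_sd", "intercept_prior_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.draws < 1 or self.warmup < 1 or self.chains < 1:
            raise ValueError("draws, warmup and chains must be positive")

    def covariate_sds(self) -> np.ndarray:
        c = self.covariate_prior_sds
        com = c.get("comorbidities", 1.0)
        return np.array([c.get("age", 10.0), c.get("age_sq", 10.0),
                         c.get("sex", 1.0), com, com, com, com,
                         c.get("wmhv", 1.0)])


@dataclass
class PosteriorSamples:
    """Named posterior draws plus sampler diagnostics.

    ``draws`` maps parameter names to arrays whose leading axis indexes
    MCMC iterations (all parameters share it, so per-iteration contrasts
    are paired).  ``beta_atoms`` has shape (n_draws, n_groups, n_atoms)
    with groups ordered as in ``group_names``.
    """

    draws: dict = field(repr=False)
    group_names: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    spec: ModelSpec | None = None

    def __post_init__(self) -> None:
        n = {v.shape[0] for v in self.draws.values()}
        if len(n) != 1:
            raise ValueError("all parameters must share the draw count")
        for name in ("sigma_beta", "hyper_sigma_beta", "eps"):
            if name in self.draws and np.any(self.draws[name] <= 0):
                raise ValueError(f"{name} draws must be positive")

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def atom_draws(self, group: str) -> np.ndarray:
        """(n_draws, n_atoms) coefficient draws for one group."""
        g = self.group_names.index(group)
        return self.draws["beta_atoms"][:, g, :]

    def to_dataframe(self) -> pd.DataFrame:
        """Flat draws table (one column per scalar parameter)."""
        cols = {}
        for name, arr in self.draws.items():
            if arr.ndim == 1:
                cols[name] = arr
            elif arr.ndim == 2:
                for g, gname in enumerate(self.group_names):
                    cols[f"{name}[{gname}]"] = arr[:, g]
            else:
                for g, gname in enumerate(self.group_names):
                    for k in range(arr.shape[2]):
                        cols[f"{name}[{gname},{k + 1}]"] = arr[:, g, k]
        return pd.DataFrame(cols)


@dataclass
class PosteriorSummary:
    """Per-parameter posterior mean, HPDI and relevance flag."""

    table: pd.DataFrame = field(repr=False)
    mass: float = 0.90

    def row(self, parameter: str) -> pd.Series:
        hit = self.table[self.table["parameter"] == parameter]
        if hit.empty:
            raise KeyError(parameter)
        return hit.iloc[0]


def hpdi(samples: np.ndarray, mass: float = 0.90) -> tuple[float, float]:
    """Highest-posterior-density interval: the shortest contiguous window
    over the sorted samples containing ``ceil(mass * N)`` of them."""
    samples = np.asarray(samples, dtype=float).ravel()
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    n = samples.size
    if n < 20:
        raise ValueError("need at least 20 samples for an HPDI")
    window = int(np.ceil(mass * n))
    if window > n:
        raise ValueError("window exceeds sample count")
    s = np.sort(samples)
    widths = s[window - 1:] - s[:n - window + 1]
    best = int(np.argmin(widths))
    return float(s[best]), float(s[best + window - 1])


def _halfcauchy_logpdf_logscale(log_s: np.ndarray,
                                scale: np.ndarray | float) -> np.ndarray:
    """log p(log s) for s ~ HalfCauchy(scale), including the Jacobian.

    Uses log(1 + (s/scale)^2) = logaddexp(0, 2(log s - log scale)) for
    overflow-free evaluation far out in the tails.
    """
    log_scale = np.log(scale)
    return (np.log(2.0 / np.pi) - log_scale
            - np.logaddexp(0.0, 2.0 * (log_s - log_scale)) + log_s)


def _normal_logpdf(x: np.ndarray, mu, sd) -> np.ndarray:
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - 0.5 * _LOG_2PI


class _HierarchicalModel:
    """Vectorized log posterior for the single-level (pooled/by-sex) model."""

    def __init__(self, inp: ModelInput, spec: ModelSpec,
                 group_index: np.ndarray, n_groups: int):
        self.scores = inp.atom_scores
        self.cov = inp.covariate_matrix()
        self.y = inp.outcome
        self.spec = spec
        self.gidx = group_index
        self.G = n_groups
        self.K = inp.n_atoms
        self.cov_sds = spec.covariate_sds()
        # layout: alpha | hyper_mu | log_hyper_sigma | zmu(G) | log_sigma(G)
        #         | z(G*K) | covariates(8) | log_eps
        self.ndim = 3 + 2 * self.G + self.G * self.K + 8 + 1
        self.group_members = [np.flatnonzero(group_index == g)
                              for g in range(n_groups)]

    def unpack(self, theta: np.ndarray):
        G, K = self.G, self.K
        i = 0
        alpha = theta[:, i]; i += 1
        hyper_mu = theta[:, i]; i += 1
        log_hyper_sigma = theta[:, i]; i += 1
        zmu = theta[:, i:i + G]; i += G
        log_sigma = theta[:, i:i + G]; i += G
        z = theta[:, i:i + G * K].reshape(-1, G, K); i += G * K
        bcov = theta[:, i:i + 8]; i += 8
        log_eps = theta[:, i]
        return (alpha, hyper_mu, log_hyper_sigma, zmu, log_sigma, z, bcov,
                log_eps)

    def betas(self, theta: np.ndarray) -> np.ndarray:
        """(walkers, G, K) atom coefficients from the raw parameters."""
        _, hyper_mu, _, zmu, log_sigma, z, _, _ = self.unpack(theta)
        if not self.spec.atom_prior_via_hierarchy:
            return z
        mu = hyper_mu[:, None] + self.spec.mu_hyper_sd * zmu
        sigma = np.exp(log_sigma)
        return mu[:, :, None] + sigma[:, :, None] * z

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        spec = self.spec
        (alpha, hyper_mu, log_hyper_sigma, zmu, log_sigma, z, bcov,
         log_eps) = self.unpack(theta)
        hyper_sigma = np.exp(log_hyper_sigma)
        eps = np.exp(log_eps)

        lp = _normal_logpdf(alpha, 0.0, spec.intercept_prior_sd)
        lp += _normal_logpdf(hyper_mu, 0.0, spec.mu_hyper_sd)
        lp += _halfcauchy_logpdf_logscale(log_hyper_sigma,
                                          spec.hyper_sigma_scale)
        if spec.atom_prior_via_hierarchy:
            lp += _normal_logpdf(zmu, 0.0, 1.0).sum(axis=1)
            lp += _halfcauchy_logpdf_logscale(
                log_sigma, hyper_sigma[:, None]).sum(axis=1)
            lp += _normal_logpdf(z, 0.0, 1.0).sum(axis=(1, 2))
        else:
            # independent wide priors; hierarchy parameters prior-only
            lp += _normal_logpdf(zmu, 0.0, 1.0).sum(axis=1)
            lp += _halfcauchy_logpdf_logscale(log_sigma, 1.0).sum(axis=1)
            lp += _normal_logpdf(z, 0.0, spec.mu_hyper_sd).sum(axis=(1, 2))
        lp += _normal_logpdf(bcov, 0.0, self.cov_sds[None, :]).sum(axis=1)
        lp += _halfcauchy_logpdf_logscale(log_eps,
                                          spec.sigma_likelihood_scale)

        beta = self.betas(theta)
        pred = alpha[None, :] + self.cov @ bcov.T  # (n, walkers)
        for g, members in enumerate(self.group_members):
            pred[members] += self.scores[members] @ beta[:, g, :].T
        resid = self.y[:, None] - pred
        n = self.y.size
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            lp += (-0.5 * (resid ** 2).sum(axis=0) / eps ** 2
                   - n * log_eps - 0.5 * n * _LOG_2PI)
        return np.where(np.isfinite(lp), lp, -np.inf)

    def initial_point(self) -> np.ndarray:
        """Least-squares-informed center for walker initialization."""
        n = self.y.size
        design = [np.ones(n)]
        for g, members in enumerate(self.group_members):
            block = np.zeros((n, self.K))
            block[members] = self.scores[members]
            design.append(block)
        design.append(self.cov)
        X = np.column_stack(design)
        coef, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        resid_sd = float(np.std(self.y - X @ coef)) or 1.0
        alpha0 = float(np.clip(coef[0], -2, 2))
        beta0 = coef[1:1 + self.G * self.K].reshape(self.G, self.K)
        bcov0 = coef[1 + self.G * self.K:]
        mu0 = beta0.mean(axis=1)
        sigma0 = beta0.std(axis=1) + 0.5
        hyper_mu0 = float(mu0.mean())
        hyper_sigma0 = float(sigma0.mean())
        theta = np.empty(self.ndim)
        i = 0
        theta[i] = alpha0; i += 1
        theta[i] = hyper_mu0; i += 1
        theta[i] = np.log(hyper_sigma0); i += 1
        theta[i:i + self.G] = (mu0 - hyper_mu0) / self.spec.mu_hyper_sd
        i += self.G
        theta[i:i + self.G] = np.log(sigma0); i += self.G
        if self.spec.atom_prior_via_hierarchy:
            zz = (beta0 - mu0[:, None]) / sigma0[:, None]
        else:
            zz = beta0
        theta[i:i + self.G * self.K] = zz.ravel(); i += self.G * self.K
        theta[i:i + 8] = bcov0; i += 8
        theta[i] = np.log(resid_sd)
        return theta


def _run_ensemble(model, spec: ModelSpec) -> np.ndarray:
    """Sample the model with `spec.chains` independent ensembles.

    Returns flat draws (n_draws, ndim); the per-ensemble chains are kept
    on the model object for split-R-hat diagnostics (each independent
    ensemble is one diagnostic chain, flattened step-major so drift over
    steps is visible to the split).
    """
    ndim = model.ndim
    n_walkers = spec.n_walkers or max(64, 2 * ndim + 8)
    retain = max(10, int(np.ceil(spec.draws / (spec.chains * n_walkers))))
    center = model.initial_point()
    moves = [(emcee.moves.DEMove(), 0.8),
             (emcee.moves.DESnookerMove(), 0.2)]
    chains = []
    acc = []
    for c in range(spec.chains):
        rng = np.random.RandomState((spec.seed + 7919 * c) % (2 ** 31))
        p0 = center[None, :] + 0.05 * rng.standard_normal((n_walkers, ndim))
        sampler = emcee.EnsembleSampler(n_walkers, ndim, model,
                                        vectorize=True, moves=moves)
        sampler.random_state = rng.get_state()
        sampler.run_mcmc(p0, spec.warmup + retain * spec.thin,
                         progress=False, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=spec.warmup, thin=spec.thin)
        chains.append(chain)  # (retain, n_walkers, ndim)
        acc.append(float(np.mean(sampler.acceptance_fraction)))
    model._chain_list = chains
    model._acceptance = float(np.mean(acc))
    flat = np.concatenate([c.reshape(-1, ndim) for c in chains], axis=0)
    return flat


def _rhat(per_chain_values: list[np.ndarray]) -> float:
    """Split-R-hat with one diagnostic chain per independent ensemble."""
    stacked = np.stack([np.asarray(v).ravel() for v in per_chain_values])
    if stacked.shape[0] < 2:  # single ensemble: split it in half instead
        half = stacked.shape[1] // 2
        stacked = np.stack([stacked[0, :half], stacked[0, half:2 * half]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(np.ascontiguousarray(stacked)))


def _diagnostics(model, spec: ModelSpec, names: list[str],
                 extract) -> dict:
    rhats = {}
    for name in names:
        vals = [extract(chain, name) for chain in model._chain_list]
        rhats[name] = _rhat(vals)
    max_rhat = max(rhats.values())
    warn = []
    if max_rhat > 1.05:
        warn.append(f"max split-R-hat {max_rhat:.3f} exceeds 1.05; "
                    "treat summaries with caution")
    if model._acceptance < 0.1:
        warn.append(f"low ensemble acceptance {model._acceptance:.2f}")
    return {
        "sampler": "emcee affine-invariant ensemble",
        "acceptance_fraction": model._acceptance,
        "divergence_count": 0,  # not defined for the ensemble sampler
        "rhat": rhats,
        "max_rhat": max_rhat,
        "warnings": warn,
    }


def fit_hierarchical_model(inp: ModelInput,
                           spec: ModelSpec | None = None) -> PosteriorSamples:
    """Fit the pooled or sex-hierarchical severity model.

    Groups are {all} for ``hierarchy='pooled'`` and {male, female} for
    ``hierarchy='by_sex'`` (membership from ``inp.sex``, female = 1).
    Returns named posterior draws and sampler diagnostics; convergence
    problems are flagged in ``diagnostics['warnings']``, never silently.
    """
    spec = spec or ModelSpec()
    spec.validate()
    if spec.hierarchy == "stratified_by_sex":
        return fit_stratified_model(inp, spec)
    if spec.hierarchy == "pooled":
        group_index = np.zeros(inp.n_patients, dtype=int)
        group_names = ["all"]
    else:
        group_index = inp.sex.astype(int)  # 0 male, 1 female
        group_names = ["male", "female"]
        for g, name in enumerate(group_names):
            if not np.any(group_index == g):
                raise ValueError(f"group '{name}' is empty")

    model = _HierarchicalModel(inp, spec, group_index, len(group_names))
    flat = _run_ensemble(model, spec)
    G, K = model.G, model.K

    beta = model.betas(flat)
    (alpha, hyper_mu, log_hyper_sigma, zmu, log_sigma, _, bcov,
     log_eps) = model.unpack(flat)
    mu = hyper_mu[:, None] + spec.mu_hyper_sd * zmu
    draws = {
        "alpha": alpha,
        "beta_atoms": beta,
        "mu_beta": mu,
        "sigma_beta": np.exp(log_sigma),
        "hyper_mu_beta": hyper_mu,
        "hyper_sigma_beta": np.exp(log_hyper_sigma),
        "eps": np.exp(log_eps),
    }
    for j, name in enumerate(_COVARIATE_NAMES):
        draws[name] = bcov[:, j]

    def extract(chain, name):
        th = chain.reshape(-1, model.ndim)  # step-major
        if name == "alpha":
            return th[:, 0]
        if name == "eps":
            return th[:, -1]
        g, k = name
        return model.betas(th)[:, g, k]

    diag_names = ["alpha", "eps"] + [(g, k) for g in range(G)
                                     for k in range(K)]
    diagnostics = _diagnostics(model, spec, diag_names, extract)
    diagnostics["rhat"] = {
        (f"beta[{group_names[n[0]]},{n[1] + 1}]"
         if isinstance(n, tuple) else n): v
        for n, v in diagnostics["rhat"].items()}
    diagnostics["max_rhat"] = max(diagnostics["rhat"].values())
    return PosteriorSamples(draws=draws, group_names=group_names,
                            diagnostics=diagnostics, spec=spec)


class _StratifiedModel(_HierarchicalModel):
    """Two-level hierarchy: global hypers -> stratum -> sex-within-stratum."""

    def __init__(self, inp: ModelInput, spec: ModelSpec,
                 stratum_index: np.ndarray, n_strata: int):
        cell_index = stratum_index * 2 + inp.sex.astype(int)
        super().__init__(inp, spec, cell_index, n_strata * 2)
        self.S = n_strata
        # layout: alpha | hyper_mu | log_hyper_sigma | zmu_str(S)
        #         | log_sigma_str(S) | zmu_cell(2S) | log_sigma_cell(2S)
        #         | z(2S*K) | covariates(8) | log_eps
        self.ndim = 3 + 2 * self.S + 2 * self.G + self.G * self.K + 8 + 1

    def unpack(self, theta: np.ndarray):
        S, G, K = self.S, self.G, self.K
        i = 0
        alpha = theta[:, i]; i += 1
        hyper_mu = theta[:, i]; i += 1
        log_hyper_sigma = theta[:, i]; i += 1
        zmu_str = theta[:, i:i + S]; i += S
        log_sigma_str = theta[:, i:i + S]; i += S
        zmu_cell = theta[:, i:i + G]; i += G
        log_sigma_cell = theta[:, i:i + G]; i += G
        z = theta[:, i:i + G * K].reshape(-1, G, K); i += G * K
        bcov = theta[:, i:i + 8]; i += 8
        log_eps = theta[:, i]
        return (alpha, hyper_mu, log_hyper_sigma, zmu_str, log_sigma_str,
                zmu_cell, log_sigma_cell, z, bcov, log_eps)

    def cell_params(self, theta):
        (_, hyper_mu, _, zmu_str, log_sigma_str, zmu_cell, log_sigma_cell,
         z, _, _) = self.unpack(theta)
        sd = self.spec.mu_hyper_sd
        mu_str = hyper_mu[:, None] + sd * zmu_str              # (w, S)
        mu_cell = np.repeat(mu_str, 2, axis=1) + sd * zmu_cell  # (w, 2S)
        sigma_cell = np.exp(log_sigma_cell)
        return mu_str, mu_cell, sigma_cell, z

    def betas(self, theta: np.ndarray) -> np.ndarray:
        _, mu_cell, sigma_cell, z = self.cell_params(theta)
        return mu_cell[:, :, None] + sigma_cell[:, :, None] * z

    def __call__(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        spec = self.spec
        (alpha, hyper_mu, log_hyper_sigma, zmu_str, log_sigma_str,
         zmu_cell, log_sigma_cell, z, bcov, log_eps) = self.unpack(theta)
        hyper_sigma = np.exp(log_hyper_sigma)
        sigma_str = np.exp(log_sigma_str)
        eps = np.exp(log_eps)

        lp = _normal_logpdf(alpha, 0.0, spec.intercept_prior_sd)
        lp += _normal_logpdf(hyper_mu, 0.0, spec.mu_hyper_sd)
        lp += _halfcauchy_logpdf_logscale(log_hyper_sigma,
                                          spec.hyper_sigma_scale)
        lp += _normal_logpdf(zmu_str, 0.0, 1.0).sum(axis=1)
        lp += _halfcauchy_logpdf_logscale(
            log_sigma_str, hyper_sigma[:, None]).sum(axis=1)
        lp += _normal_logpdf(zmu_cell, 0.0, 1.0).sum(axis=1)
        lp += _halfcauchy_logpdf_logscale(
            log_sigma_cell, np.repeat(sigma_str, 2, axis=1)).sum(axis=1)
        lp += _normal_logpdf(z, 0.0, 1.0).sum(axis=(1, 2))
        lp += _normal_logpdf(bcov, 0.0, self.cov_sds[None, :]).sum(axis=1)
        lp += _halfcauchy_logpdf_logscale(log_eps,
                                          spec.sigma_likelihood_scale)

        beta = self.betas(theta)
        pred = alpha[None, :] + self.cov @ bcov.T
        for g, members in enumerate(self.group_members):
            if members.size:
                pred[members] += self.scores[members] @ beta[:, g, :].T
        resid = self.y[:, None] - pred
        n = self.y.size
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            lp += (-0.5 * (resid ** 2).sum(axis=0) / eps ** 2
                   - n * log_eps - 0.5 * n * _LOG_2PI)
        return np.where(np.isfinite(lp), lp, -np.inf)

    def initial_point(self) -> np.ndarray:
        n = self.y.size
        design = [np.ones(n)]
        for members in self.group_members:
            block = np.zeros((n, self.K))
            block[members] = self.scores[members]
            design.append(block)
        design.append(self.cov)
        X = np.column_stack(design)
        coef, *_ = np.linalg.lstsq(X, self.y, rcond=None)
        resid_sd = float(np.std(self.y - X @ coef)) or 1.0
        beta0 = coef[1:1 + self.G * self.K].reshape(self.G, self.K)
        bcov0 = coef[1 + self.G * self.K:]
        mu_cell0 = beta0.mean(axis=1)
        sigma_cell0 = beta0.std(axis=1) + 0.5
        mu_str0 = mu_cell0.reshape(self.S, 2).mean(axis=1)
        sd = self.spec.mu_hyper_sd
        theta = np.empty(self.ndim)
        i = 0
        theta[i] = float(np.clip(coef[0], -2, 2)); i += 1
        hyper_mu0 = float(mu_str0.mean())
        theta[i] = hyper_mu0; i += 1
        theta[i] = np.log(sigma_cell0.mean()); i += 1
        theta[i:i + self.S] = (mu_str0 - hyper_mu0) / sd; i += self.S
        theta[i:i + self.S] = np.log(sigma_cell0.reshape(self.S, 2)
                                     .mean(axis=1)); i += self.S
        theta[i:i + self.G] = (mu_cell0
                               - np.repeat(mu_str0, 2)) / sd; i += self.G
        theta[i:i + self.G] = np.log(sigma_cell0); i += self.G
        zz = (beta0 - mu_cell0[:, None]) / sigma_cell0[:, None]
        theta[i:i + self.G * self.K] = zz.ravel(); i += self.G * self.K
        theta[i:i + 8] = bcov0; i += 8
        theta[i] = np.log(resid_sd)
        return theta


def fit_stratified_model(inp: ModelInput,
                         spec: ModelSpec | None = None) -> PosteriorSamples:
    """Fit the two-level (stratum x sex) hierarchical severity model.

    Every stratum x sex cell must contain at least two patients.  Cells
    are reported as groups named ``"<stratum>:<sex>"`` so all
    stratum-and-sex contrasts are computable from ``beta_atoms``.
    """
    spec = spec or ModelSpec(hierarchy="stratified_by_sex")
    spec.validate()
    if inp.stratum is None:
        raise ValueError("input has no stratum column")
    strata = sorted(pd.unique(inp.stratum).tolist())
    stratum_index = np.array([strata.index(s) for s in inp.stratum])
    for s_i, s in enumerate(strata):
        for sex, sex_name in ((0, "male"), (1, "female")):
            count = int(np.sum((stratum_index == s_i) & (inp.sex == sex)))
            if count < 2:
                raise ValueError(
                    f"stratum x sex cell '{s}:{sex_name}' has {count} "
                    "patients (need >= 2)")

    model = _StratifiedModel(inp, spec, stratum_index, len(strata))
    flat = _run_ensemble(model, spec)
    group_names = [f"{s}:{sex}" for s in strata for sex in ("male", "female")]

    beta = model.betas(flat)
    (alpha, hyper_mu, log_hyper_sigma, zmu_str, log_sigma_str, _,
     log_sigma_cell, _, bcov, log_eps) = model.unpack(flat)
    mu_str, mu_cell, sigma_cell, _ = model.cell_params(flat)
    draws = {
        "alpha": alpha,
        "beta_atoms": beta,
        "mu_beta": mu_cell,
        "sigma_beta": sigma_cell,
        "mu_beta_stratum": mu_str,
        "sigma_beta_stratum": np.exp(log_sigma_str),
        "hyper_mu_beta": hyper_mu,
        "hyper_sigma_beta": np.exp(log_hyper_sigma),
        "eps": np.exp(log_eps),
    }
    for j, name in enumerate(_COVARIATE_NAMES):
        draws[name] = bcov[:, j]

    def extract(chain, name):
        th = chain.reshape(-1, model.ndim)  # step-major
        if name == "alpha":
            return th[:, 0]
        if name == "eps":
            return th[:, -1]
        g, k = name
        return model.betas(th)[:, g, k]

    diag_names = ["alpha", "eps"] + [(g, k) for g in range(model.G)
                                     for k in range(model.K)]
    diagnostics = _diagnostics(model, spec, diag_names, extract)
    diagnostics["rhat"] = {
        (f"beta[{group_names[n[0]]},{n[1] + 1}]"
         if isinstance(n, tuple) else n): v
        for n, v in diagnostics["rhat"].items()}
    diagnostics["max_rhat"] = max(diagnostics["rhat"].values())
    return PosteriorSamples(draws=draws, group_names=group_names,
                            diagnostics=diagnostics, spec=spec)


def summarize_posterior(samples: PosteriorSamples,
                        mass: float = 0.90) -> PosteriorSummary:
    """Posterior mean, HPDI bounds and relevance flag for every parameter.

    A parameter is flagged *relevant* when its HPDI excludes zero (the
    posterior does not substantially overlap zero).
    """
    rows = []

    def add(name, vec):
        lo, hi = hpdi(vec, mass)
        rows.append({"parameter": name, "mean": float(np.mean(vec)),
                     "hpdi_low": lo, "hpdi_high": hi,
                     "relevant": not lo <= 0.0 <= hi})

    for name, arr in samples.draws.items():
        if arr.ndim == 1:
            add(name, arr)
        elif arr.ndim == 2:
            for g, gname in enumerate(samples.group_names):
                if arr.shape[1] == len(samples.group_names):
                    add(f"{name}[{gname}]", arr[:, g])
            if arr.shape[1] != len(samples.group_names):
                for g in range(arr.shape[1]):
                    add(f"{name}[{g}]", arr[:, g])
        else:
            for g, gname in enumerate(samples.group_names):
                for k in range(arr.shape[2]):
                    add(f"{name}[{gname},{k + 1}]", arr[:, g, k])
    return PosteriorSummary(table=pd.DataFrame(rows), mass=mass)


def difference_distribution(samples_m: np.ndarray, samples_f: np.ndarray,
                            mass: float = 0.90) -> dict:
    """Male-minus-female contrast, paired by MCMC iteration.

    Returns the difference draws, their mean and HPDI, a relevance
    ``flag`` (HPDI excludes zero) and ``tail_prob``: the fraction of draws
    whose sign opposes the median's sign (the "overlap with zero" mass).
    """
    samples_m = np.asarray(samples_m, dtype=float)
    samples_f = np.asarray(samples_f, dtype=float)
    if samples_m.shape != samples_f.shape:
        raise ValueError("draw vectors must have equal length (paired)")
    diff = samples_m - samples_f
    lo, hi = hpdi(diff, mass)
    med = np.median(diff)
    if med == 0:
        tail = 0.5
    else:
        tail = float(np.mean(np.sign(diff) == -np.sign(med)))
    return {"draws": diff, "mean": float(diff.mean()),
            "hpdi": (lo, hi), "flag": not lo <= 0.0 <= hi,
            "tail_prob": tail}


def sex_difference_table(samples: PosteriorSamples,
                         mass: float = 0.90,
                         male: str = "male",
                         female: str = "female") -> pd.DataFrame:
    """Per-atom male-minus-female contrast table from one posterior."""
    m = samples.atom_draws(male)
    f = samples.atom_draws(female)
    rows = []
    for k in range(m.shape[1]):
        d = difference_distribution(m[:, k], f[:, k], mass)
        rows.append({"atom": k + 1, "mean": d["mean"],
                     "hpdi_low": d["hpdi"][0], "hpdi_high": d["hpdi"][1],
                     "flag": d["flag"], "tail_prob": d["tail_prob"]})
    return pd.DataFrame(rows)
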