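"""Bayesian Cmax error-distribution model: specification, fitting, posterior prediction.

The model quantifies the error of physiologically based kinetic (PBK) plasma-Cmax
estimates at three parameterization levels (L1: in silico only, L2: + in vitro,
L3: + clinical calibration). Everything lives on the log10(µM) scale. For chemical
*i* under exposure *j*, with true population-average log10 Cmax ``zeta``:

    zhat_clinical ~ Normal(zeta,                 sigma_clinical)
    zhat_L3       ~ Normal(zeta + alpha_L3,      sigma_L3pop)
    zhat_L2       ~ Normal(zhat_L3 + alpha_L2,   sigma * f_L2L3 / (beta + f_L2L3))
    zhat_L1       ~ Normal(zhat_L2 + alpha_L1,   sigma * f_L1L2 / (beta + f_L1L2))

where ``f`` is the fraction of PBK parameters whose values differ between the two
adjacent levels (the gap standard deviation vanishes when all parameters are
shared and saturates at ``sigma``). The ``alpha`` terms capture level-specific
bias and the error distributions are chemical- and exposure-agnostic.

Because every layer is Gaussian, the latent true values and any missing
observations can be marginalized in closed form, leaving a 7-dimensional
hyperparameter posterior which is sampled with the affine-invariant ensemble
sampler (emcee). Latent and missing quantities are reinstated afterwards by
exact conditional-normal draws, so the joint posterior is identical to sampling
the full hierarchy directly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import emcee
import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import CmaxRecord, Dataset

__all__ = [
    "PARAM_NAMES",
    "LEVELS",
    "ModelSpec",
    "McmcConfig",
    "PosteriorFit",
    "PredictiveDistribution",
    "level_gap_sd",
    "fit_error_model",
    "posterior_predict_cmax",
    "predict_withheld_measurement",
]

PARAM_NAMES = (
    "sigma_clinical",
    "alpha_L1",
    "alpha_L2",
    "alpha_L3",
    "sigma_L3pop",
    "sigma",
    "beta",
)
LEVELS = ("L1", "L2", "L3")

# component order in the per-scenario observation vector
_COMPONENTS = ("clinical", "L3", "L2", "L1")
_FIELD_OF = {
    "clinical": "zhat_clinical",
    "L3": "zhat_L3",
    "L2": "zhat_L2",
    "L1": "zhat_L1",
}


def level_gap_sd(sigma: float, beta: float, f: float) -> float:
    """Standard deviation of the gap between predictions at adjacent PBK levels.

    ``sigma * f / (beta + f)``: zero when no parameters change (f = 0), strictly
    increasing in ``f`` and bounded above by ``sigma``. The ``beta = f = 0``
    corner returns 0 (limit convention).
    """
    sigma, beta, f = np.asarray(sigma, float), np.asarray(beta, float), np.asarray(f, float)
    denom = beta + f
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, sigma * f / np.where(denom > 0, denom, 1.0), 0.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelSpec:
    """Priors and unknown-fraction defaults for the Cmax error model.

    The clinical-noise prior InverseGamma(4.6, 0.22) places ~95% of its mass on
    sigma_clinical in [0.0225, 0.155] log10 units (between a 1.1-fold and a
    2-fold measurement error at 95% probability). Bias terms are half-normal,
    hence nonnegative: PBK estimates may overpredict but the prior does not
    allow systematic underprediction.
    """

    prior_sigma_clinical: tuple[float, float] = (4.6, 0.22)  # inv-gamma shape, scale
    prior_alpha_scale: float = 0.5
    prior_sigma_L3pop_scale: float = 1.0
    prior_sigma_scale: float = 1.0
    prior_beta_scale: float = 0.5
    default_f_L2L3: float = 0.5
    default_f_L1L2: float = 1.0
    zeta_prior_sd: float = 10.0  # effectively flat over the 0.004-4000 µM range

    def __post_init__(self):
        scales = (
            *self.prior_sigma_clinical,
            self.prior_alpha_scale,
            self.prior_sigma_L3pop_scale,
            self.prior_sigma_scale,
            self.prior_beta_scale,
            self.zeta_prior_sd,
        )
        if any(s <= 0 for s in scales):
            raise ValueError("all prior scales must be > 0")
        if not (0 <= self.default_f_L2L3 <= 1 and 0 <= self.default_f_L1L2 <= 1):
            raise ValueError("fraction defaults must lie in [0, 1]")


@dataclass(frozen=True)
class McmcConfig:
    """Ensemble-sampler configuration.

    ``chains * samples`` posterior draws are retained, thinned from
    ``samples`` post-warmup ensemble steps of ``8 * chains`` walkers.
    """

    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 1234

    @property
    def nwalkers(self) -> int:
        return 8 * self.chains

    @property
    def n_draws(self) -> int:
        return self.chains * self.samples


# --------------------------------------------------------------------------
# marginal likelihood machinery
# --------------------------------------------------------------------------


def _record_design(rec: CmaxRecord, spec: ModelSpec):
    """(observed-index array, y vector, f_L2L3, f_L1L2) for one record."""
    idx, y = [], []
    for k, comp in enumerate(_COMPONENTS):
        v = getattr(rec, _FIELD_OF[comp])
        if v is not None:
            idx.append(k)
            y.append(float(v))
    f23 = rec.f_L2L3 if rec.f_L2L3 is not None else spec.default_f_L2L3
    f12 = rec.f_L1L2 if rec.f_L1L2 is not None else spec.default_f_L1L2
    return np.array(idx), np.array(y), float(f23), float(f12)


def _full_moments(params: dict[str, np.ndarray], f23, f12, tau: float):
    """Mean offsets (..., 4) and covariance (..., 4, 4) of the 4-component
    observation vector [clinical, L3, L2, L1], with the latent zeta (prior
    Normal(0, tau)) marginalized out. Broadcasts over leading dimensions of the
    parameter arrays and of f23/f12."""
    sc, a1, a2, a3 = (params[k] for k in ("sigma_clinical", "alpha_L1", "alpha_L2", "alpha_L3"))
    s3, sg, be = (params[k] for k in ("sigma_L3pop", "sigma", "beta"))
    s2 = level_gap_sd(sg, be, f23)
    s1 = level_gap_sd(sg, be, f12)
    shape = np.broadcast_shapes(
        *(np.shape(x) for x in (sc, a1, a2, a3, s3, sg, be, s2, s1))
    )
    zero = np.zeros(shape)
    a = np.stack([zero, a3 + zero, a3 + a2 + zero, a3 + a2 + a1 + zero], axis=-1)
    v3 = s3**2 + zero
    v2 = v3 + s2**2
    v1 = v2 + s1**2
    cov = np.full(shape + (4, 4), tau**2)
    cov[..., 0, 0] += sc**2
    cov[..., 1, 1] += v3
    cov[..., 2, 2] += v2
    cov[..., 3, 3] += v1
    # tiny nugget keeps the marginal covariance nonsingular when a gap sd is 0
    for i in range(4):
        cov[..., i, i] += 1e-8 + 1e-9 * cov[..., i, i]
    for i, j, v in ((1, 2, v3), (1, 3, v3), (2, 3, v2)):
        cov[..., i, j] += v
        cov[..., j, i] += v
    return a, cov


class _MarginalLikelihood:
    """Vectorized log marginal likelihood over walker parameter arrays.

    Scenarios are grouped by missingness pattern so each group needs a single
    batched Gaussian density evaluation per call.
    """

    def __init__(self, ds: Dataset, spec: ModelSpec):
        self.spec = spec
        groups: dict[tuple, list] = {}
        for rec in ds.scenarios:
            idx, y, f23, f12 = _record_design(rec, spec)
            groups.setdefault(tuple(idx), []).append((y, f23, f12))
        self.groups = [
            (np.array(k), np.array([g[0] for g in v]), np.array([g[1] for g in v]),
             np.array([g[2] for g in v]))
            for k, v in groups.items()
        ]

    def __call__(self, params: dict[str, np.ndarray]) -> np.ndarray:
        tau = self.spec.zeta_prior_sd
        total = 0.0
        for idx, y, f23, f12 in self.groups:
            # shapes: params (W,), f (G,) -> (G, W)
            p = {k: v[None, :] for k, v in params.items()}
            a, cov = _full_moments(p, f23[:, None], f12[:, None], tau)
            a = a[..., idx]
            cov = cov[..., idx[:, None], idx[None, :]]
            r = y[:, None, :] - a
            sign, logdet = np.linalg.slogdet(cov)
            sol = np.linalg.solve(cov, r[..., None])[..., 0]
            quad = np.einsum("...i,...i->...", r, sol)
            k = len(idx)
            ll = -0.5 * (k * np.log(2 * np.pi) + logdet + quad)
            ll = np.where(sign > 0, ll, -np.inf)
            total = total + ll.sum(axis=0)
        return total + np.zeros(
            np.shape(params["sigma"])
        )  # ensure (W,) even for empty datasets


def _log_prior(params: dict[str, np.ndarray], spec: ModelSpec) -> np.ndarray:
    shape_a, scale_a = spec.prior_sigma_clinical
    lp = stats.invgamma.logpdf(params["sigma_clinical"], shape_a, scale=scale_a)
    for name, scale in (
        ("alpha_L1", spec.prior_alpha_scale),
        ("alpha_L2", spec.prior_alpha_scale),
        ("alpha_L3", spec.prior_alpha_scale),
        ("sigma_L3pop", spec.prior_sigma_L3pop_scale),
        ("sigma", spec.prior_sigma_scale),
        ("beta", spec.prior_beta_scale),
    ):
        lp = lp + stats.halfnorm.logpdf(params[name], scale=scale)
    return lp


# --------------------------------------------------------------------------
# posterior containers
# --------------------------------------------------------------------------


class PredictiveDistribution:
    """Per-scenario predictive distribution of log10(µM) Cmax.

    Represented as an equally weighted normal mixture: one (mean, sd) component
    per retained posterior draw. ``quantile`` inverts the exact mixture CDF, so
    quantiles are monotone and, for a degenerate single-component fit, agree
    with the closed-form normal expressions to solver precision.
    """

    def __init__(self, scenario_key, target: str, mus, sds, rng: np.random.Generator):
        mus = np.atleast_1d(np.asarray(mus, float))
        sds = np.atleast_1d(np.asarray(sds, float))
        if mus.shape != sds.shape or mus.size == 0:
            raise ValueError("mus and sds must be equal-length, nonempty")
        if not (np.all(np.isfinite(mus)) and np.all(sds > 0)):
            raise ValueError("predictive components must be finite with sd > 0")
        if target not in ("population_average", "withheld_measurement"):
            raise ValueError(f"unknown target {target!r}")
        self.scenario_key = scenario_key
        self.target = target
        self.mus = mus
        self.sds = sds
        self._draws = mus + sds * rng.standard_normal(mus.shape)

    @property
    def draws(self) -> np.ndarray:
        """One log10 Cmax sample per posterior draw."""
        return self._draws

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        z = (x[..., None] - self.mus) / self.sds
        return stats.norm.cdf(z).mean(axis=-1)

    def quantile(self, q):
        """Equal-tailed mixture quantile(s); monotone in q."""
        qs = np.atleast_1d(np.asarray(q, float))
        if np.any((qs <= 0) | (qs >= 1)):
            raise ValueError("quantile levels must lie in (0, 1)")
        lo = float(np.min(self.mus - 12 * self.sds))
        hi = float(np.max(self.mus + 12 * self.sds))
        out = np.array(
            [optimize.brentq(lambda x, p=p: self.cdf(x) - p, lo, hi, xtol=1e-12) for p in qs]
        )
        return out if np.ndim(q) else float(out[0])

    def mean(self) -> float:
        return float(self.mus.mean())

    def sd(self) -> float:
        return float(np.sqrt(np.mean(self.sds**2 + self.mus**2) - self.mus.mean() ** 2))

    def interval(self, mass: float) -> tuple[float, float]:
        a = (1 - mass) / 2
        return self.quantile(a), self.quantile(1 - a)


@dataclass
class PosteriorFit:
    """Joint posterior draws of the Cmax error model.

    ``draws`` holds one row per retained sample: the 7 hyperparameters, the
    latent true log10 Cmax ``zeta[<chemical>|<route>|<exposure>]`` for every
    scenario, and imputed values for every missing L3 / clinical observation.
    """

    draws: pd.DataFrame
    diagnostics: dict
    seed: int
    chains: int
    converged: bool
    spec: ModelSpec = field(default_factory=ModelSpec)
    dataset: Optional[Dataset] = None

    def param_array(self, name: str) -> np.ndarray:
        return self.draws[name].to_numpy()

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {k: self.param_array(k) for k in PARAM_NAMES}

    @property
    def n_draws(self) -> int:
        return len(self.draws)

    def rng_for(self, *context) -> np.random.Generator:
        """Deterministic substream derived from the fit seed and a context tag."""
        tag = zlib.crc32("|".join(str(c) for c in context).encode())
        return np.random.default_rng([self.seed, tag])

    @classmethod
    def from_fixed_params(
        cls,
        params: dict[str, float],
        dataset: Optional[Dataset] = None,
        spec: Optional[ModelSpec] = None,
        seed: int = 0,
    ) -> "PosteriorFit":
        """Degenerate single-draw fit with all hyperparameters fixed.

        Useful for closed-form checks: predictives from such a fit are exact
        normal distributions.
        """
        spec = spec or ModelSpec()
        row = {k: float(params.get(k, 0.0)) for k in PARAM_NAMES}
        for sd_name in ("sigma_clinical", "sigma_L3pop"):
            if row[sd_name] <= 0:
                raise ValueError(f"{sd_name} must be > 0")
        fit = cls(
            draws=pd.DataFrame([row]),
            diagnostics={},
            seed=seed,
            chains=1,
            converged=True,
            spec=spec,
            dataset=dataset,
        )
        if dataset is not None:
            _attach_latents(fit, dataset)
        return fit

    # ------ export ------

    def save(self, out_dir) -> None:
        """Flat CSV of draws plus a JSON diagnostics sidecar."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.draws.to_csv(out / "posterior_draws.csv", index=False)
        meta = {
            "seed": self.seed,
            "chains": self.chains,
            "converged": self.converged,
            "diagnostics": self.diagnostics,
        }
        (out / "diagnostics.json").write_text(json.dumps(meta, indent=2))


# --------------------------------------------------------------------------
# conditional (latent) computations
# --------------------------------------------------------------------------


def _conditional_zeta(rec: CmaxRecord, params: dict[str, np.ndarray], spec: ModelSpec):
    """Posterior mean and sd of the true zeta given the record's observations,
    per hyperparameter draw. Cov(zeta, every observed component) = tau^2."""
    idx, y, f23, f12 = _record_design(rec, spec)
    if idx.size == 0:
        raise ValueError(f"scenario {rec.key} has no observations to condition on")
    tau = spec.zeta_prior_sd
    a, cov = _full_moments(params, f23, f12, tau)
    a = a[..., idx]
    cov = cov[..., idx[:, None], idx[None, :]]
    r = (y - a)[..., None]
    sol_r = np.linalg.solve(cov, r)[..., 0]
    ones = np.ones(idx.size)
    sol_1 = np.linalg.solve(cov, np.broadcast_to(ones, a.shape)[..., None])[..., 0]
    mu = tau**2 * sol_r.sum(axis=-1)
    var = tau**2 - tau**4 * sol_1.sum(axis=-1)
    return mu, np.sqrt(np.maximum(var, 1e-300))


def _conditional_missing(
    rec: CmaxRecord, params: dict[str, np.ndarray], spec: ModelSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Exact conditional-normal draws of missing clinical / L3 observations."""
    obs_idx, y, f23, f12 = _record_design(rec, spec)
    miss = [k for k, comp in enumerate(_COMPONENTS[:2]) if getattr(rec, _FIELD_OF[comp]) is None]
    if not miss:
        return {}
    miss_idx = np.array(miss)
    a, cov = _full_moments(params, f23, f12, spec.zeta_prior_sd)
    a_o, a_m = a[..., obs_idx], a[..., miss_idx]
    S_oo = cov[..., obs_idx[:, None], obs_idx[None, :]]
    S_mo = cov[..., miss_idx[:, None], obs_idx[None, :]]
    S_mm = cov[..., miss_idx[:, None], miss_idx[None, :]]
    sol = np.linalg.solve(S_oo, (y - a_o)[..., None])[..., 0]
    mu = a_m + np.einsum("...mo,...o->...m", S_mo, sol)
    sol_S = np.linalg.solve(S_oo, np.swapaxes(S_mo, -1, -2))
    # full conditional covariance (both clinical and L3 may be missing jointly)
    cov_c = S_mm - np.einsum("...mo,...on->...mn", S_mo, sol_S)
    L = np.linalg.cholesky(cov_c + 1e-12 * np.eye(len(miss)))
    z = rng.standard_normal(mu.shape)
    draws = mu + np.einsum("...mn,...n->...m", L, z)
    return {
        _FIELD_OF[_COMPONENTS[k]]: draws[..., j] for j, k in enumerate(miss_idx)
    }


def _key_tag(key) -> str:
    return "|".join(key)


def _attach_latents(fit: PosteriorFit, ds: Dataset) -> None:
    params = fit.params
    new_cols: dict[str, np.ndarray] = {}
    for rec in ds.scenarios:
        tag = _key_tag(rec.key)
        mu, sd = _conditional_zeta(rec, params, fit.spec)
        rng = fit.rng_for("zeta", tag)
        new_cols[f"zeta[{tag}]"] = mu + sd * rng.standard_normal(mu.shape)
        imputed = _conditional_missing(rec, params, fit.spec, fit.rng_for("impute", tag))
        for field_name, vals in imputed.items():
            new_cols[f"{field_name}[{tag}]"] = vals
    fit.draws = pd.concat([fit.draws, pd.DataFrame(new_cols)], axis=1)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------


def fit_error_model(
    ds: Dataset,
    spec: Optional[ModelSpec] = None,
    mcmc: Optional[McmcConfig] = None,
) -> PosteriorFit:
    """Sample the joint posterior of the Cmax error model.

    Missing L3 and clinical values are treated as latent and imputed; unknown
    parameter-change fractions are replaced by the ModelSpec defaults. On an
    empty dataset the posterior equals the prior. Non-convergence (split-R-hat
    above 1.01 for any hyperparameter) sets ``converged=False`` on the returned
    fit rather than raising.
    """
    spec = spec or ModelSpec()
    mcmc = mcmc or McmcConfig()
    loglik = _MarginalLikelihood(ds, spec)
    ndim = len(PARAM_NAMES)

    def log_prob(x: np.ndarray) -> np.ndarray:
        # x: (W, 7) log-parameters
        bad = np.any(np.abs(x) > 20, axis=-1)
        xc = np.clip(x, -20, 20)
        params = {k: np.exp(xc[:, i]) for i, k in enumerate(PARAM_NAMES)}
        lp = _log_prior(params, spec) + xc.sum(axis=-1)  # + log-Jacobian
        lp[bad] = -np.inf
        out = np.full(x.shape[0], -np.inf)
        ok = np.isfinite(lp) & (lp > -1e12)  # skip the likelihood where the prior vetoes
        if np.any(ok):
            ll = loglik({k: v[ok] for k, v in params.items()})
            out[ok] = lp[ok] + ll
        return np.where(np.isfinite(out), out, -np.inf)

    rng = np.random.default_rng(mcmc.seed)
    shape_a, scale_a = spec.prior_sigma_clinical
    init = np.column_stack(
        [
            np.log(stats.invgamma.rvs(shape_a, scale=scale_a, size=mcmc.nwalkers, random_state=rng)),
        ]
        + [
            np.log(
                np.abs(rng.standard_normal(mcmc.nwalkers)) * s + 1e-3
            )
            for s in (
                spec.prior_alpha_scale,
                spec.prior_alpha_scale,
                spec.prior_alpha_scale,
                spec.prior_sigma_L3pop_scale,
                spec.prior_sigma_scale,
                spec.prior_beta_scale,
            )
        ]
    )
    sampler = emcee.EnsembleSampler(
        mcmc.nwalkers, ndim, log_prob, vectorize=True,
    )
    sampler.random_state = np.random.RandomState(mcmc.seed).get_state()
    state = sampler.run_mcmc(init, mcmc.warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, mcmc.samples, progress=False)
    chain = sampler.get_chain()  # (steps, walkers, ndim), log scale

    diagnostics, converged = _diagnose(chain, mcmc.chains)

    flat = np.exp(chain.reshape(-1, ndim))
    take = np.linspace(0, flat.shape[0] - 1, mcmc.n_draws).astype(int)
    draws = pd.DataFrame(flat[take], columns=list(PARAM_NAMES))

    fit = PosteriorFit(
        draws=draws,
        diagnostics=diagnostics,
        seed=mcmc.seed,
        chains=mcmc.chains,
        converged=converged,
        spec=spec,
        dataset=ds,
    )
    if len(ds.scenarios):
        _attach_latents(fit, ds)
    return fit


def _diagnose(chain: np.ndarray, n_groups: int) -> tuple[dict, bool]:
    """Split-R-hat and ESS for ensemble chains.

    Walker series are thinned by the integrated autocorrelation time (so draws
    within a series are near-independent), then walkers are concatenated into
    ``n_groups`` pseudo-chains for the between/within comparison.
    """
    import logging
    import warnings

    import arviz as az

    logging.getLogger("emcee.autocorr").setLevel(logging.ERROR)
    steps, nwalkers, ndim = chain.shape
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            tau = emcee.autocorr.integrated_time(chain, quiet=True)
            thin = max(1, int(np.ceil(np.nanmax(tau))))
        except Exception:
            thin = max(1, steps // 20)
    thinned = chain[::thin]
    groups = np.array_split(np.arange(nwalkers), max(2, n_groups))
    pseudo = np.stack(
        [thinned[:, g, :].transpose(1, 0, 2).reshape(-1, ndim) for g in groups]
    )
    posterior = {name: pseudo[:, :, i] for i, name in enumerate(PARAM_NAMES)}
    idata = az.from_dict(posterior=posterior)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    diagnostics = {
        name: {
            "rhat": float(rhat[name].values),
            "ess_bulk": float(ess[name].values),
        }
        for name in PARAM_NAMES
    }
    converged = all(np.isfinite(d["rhat"]) and d["rhat"] <= 1.01 for d in diagnostics.values())
    return diagnostics, converged


# --------------------------------------------------------------------------
# prediction
# --------------------------------------------------------------------------


def posterior_predict_cmax(fit: PosteriorFit, scenario: CmaxRecord) -> PredictiveDistribution:
    """Predictive distribution of the population-average log10 Cmax.

    Conditions on the scenario's available observations using the posterior
    hyperparameter draws; works identically for scenarios inside or outside
    the training set (the likelihood factorizes across scenarios).
    """
    if not scenario.observed_levels():
        raise ValueError(f"scenario {scenario.key} has no observations")
    mu, sd = _conditional_zeta(scenario, fit.params, fit.spec)
    rng = fit.rng_for("predict", _key_tag(scenario.key))
    return PredictiveDistribution(scenario.key, "population_average", mu, sd, rng)


def predict_withheld_measurement(
    fit_reduced: PosteriorFit, scenario: CmaxRecord, level_context: str
) -> PredictiveDistribution:
    """Predictive distribution of a withheld clinically measured Cmax.

    Conditions only on PBK estimates at levels <= ``level_context`` (the
    clinical value and higher levels are dropped from the scenario), then
    convolves the population-average predictive with the clinical measurement
    noise, draw by draw.
    """
    if level_context not in LEVELS:
        raise ValueError(f"level_context must be one of {LEVELS}")
    if getattr(scenario, _FIELD_OF[level_context]) is None:
        raise ValueError(f"scenario {scenario.key} has no {level_context} observation")
    keep_rank = LEVELS.index(level_context)  # L1 -> 0, L2 -> 1, L3 -> 2
    update = {"zhat_clinical": None}
    for rank, lev in enumerate(LEVELS):
        if rank > keep_rank:
            update[_FIELD_OF[lev]] = None
    reduced = scenario.model_copy(update=update)
    mu, sd = _conditional_zeta(reduced, fit_reduced.params, fit_reduced.spec)
    sd_meas = np.sqrt(sd**2 + fit_reduced.param_array("sigma_clinical") ** 2)
    rng = fit_reduced.rng_for("withheld", _key_tag(scenario.key), level_context)
    return PredictiveDistribution(
        scenario.key, "withheld_measurement", mu, sd_meas, rng
    )
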