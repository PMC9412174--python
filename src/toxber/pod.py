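"""Point-of-departure estimation: screening rules, Bayesian Hill fits, minimum PODs.

Covers the in vitro pharmacological profiling (IPP) workflow — the >50%
specific-binding follow-up rule, the 10 vs 100 µM screening-concentration
choice, and Bayesian Hill concentration-response fits yielding EC50 (agonist
mode) or IC50 (antagonist mode) posteriors — plus aggregation of platform PODs
into the minimum POD that drives the bioactivity exposure ratio. PODs from the
cell-stress and transcriptomics platforms enter as precomputed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import emcee
import numpy as np
from scipy import stats

from .data import PODRecord, Platform

__all__ = [
    "ConcentrationResponse",
    "HillFitResult",
    "HillMcmcConfig",
    "screening_followup",
    "select_screening_concentration",
    "fit_hill",
    "min_platform_pod",
]


@dataclass(frozen=True)
class ConcentrationResponse:
    """One replicate concentration-response curve (µM concentrations, % response)."""

    concentrations: np.ndarray
    responses: np.ndarray
    mode: str = "antagonist"  # 'agonist' -> EC50, 'antagonist' -> IC50
    replicate_id: int = 0

    def __post_init__(self):
        c = np.asarray(self.concentrations, float)
        r = np.asarray(self.responses, float)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)
        if c.shape != r.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(c <= 0) or not np.all(np.isfinite(c)):
            raise ValueError("concentrations must be finite and > 0 µM")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        if self.mode not in ("agonist", "antagonist"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class HillFitResult:
    """Posterior draws of the half-maximal concentration (EC50/IC50) and slope."""

    xc50_draws: np.ndarray  # µM
    slope_draws: np.ndarray
    uninformative: bool
    mode: str

    @property
    def point_estimate(self) -> float:
        """Posterior median xc50 in µM."""
        return float(np.median(self.xc50_draws))


@dataclass(frozen=True)
class HillMcmcConfig:
    walkers: int = 24
    warmup: int = 800
    samples: int = 800
    seed: int = 1234
    n_draws: int = 2000


def screening_followup(specific_binding_pct: float) -> bool:
    """Follow up a screening assay iff specific binding strictly exceeds 50%."""
    if not np.isfinite(specific_binding_pct):
        raise ValueError("specific binding percentage must be finite")
    return float(specific_binding_pct) > 50.0


def select_screening_concentration(min_cytotoxic_conc_um: Optional[float]) -> float:
    """Screening concentration (µM) for the pharmacological profiling panel.

    The standard default is 10 µM; chemicals whose cytotoxicity only appears
    above 100 µM (or never, up to 100 µM) are screened at 100 µM so low-potency
    liabilities are not missed.
    """
    if min_cytotoxic_conc_um is None:
        return 100.0
    if min_cytotoxic_conc_um <= 0:
        raise ValueError("cytotoxic concentration must be > 0 µM")
    return 100.0 if min_cytotoxic_conc_um > 100.0 else 10.0


# --------------------------------------------------------------------------
# Bayesian Hill fit
# --------------------------------------------------------------------------

#: parameters: log10 xc50, log slope, low (%), high (%), log noise sd (%)
_NPAR = 5


def _hill_mean(theta, logc, mode):
    l10xc50, logh, low, high = theta[..., 0], theta[..., 1], theta[..., 2], theta[..., 3]
    h = np.exp(logh)
    expo = np.clip((l10xc50[..., None] - logc) * h[..., None], -300, 300)
    frac = 1.0 / (1.0 + 10.0**expo)
    if mode == "antagonist":
        frac = 1.0 - frac
    return low[..., None] + (high[..., None] - low[..., None]) * frac


def fit_hill(
    cr: ConcentrationResponse | Sequence[ConcentrationResponse],
    mcmc: Optional[HillMcmcConfig] = None,
) -> HillFitResult:
    """Bayesian Hill fit of concentration-response data.

    response = low + (high - low) * c^h / (xc50^h + c^h) for agonist mode, with
    the decreasing form for antagonist mode. Priors: log10(xc50) ~
    Normal(log10(median tested concentration), 1); slope ~ LogNormal(ln 1, 0.5);
    low ~ Normal(0, 5)%; high ~ Normal(100, 5)%; noise ~ HalfNormal(0, 10)%.
    Replicates may be passed as a sequence and are pooled. Flat data leave the
    xc50 posterior prior-dominated; the result is then flagged uninformative.
    """
    curves = [cr] if isinstance(cr, ConcentrationResponse) else list(cr)
    if not curves:
        raise ValueError("no concentration-response data supplied")
    mode = curves[0].mode
    if any(c.mode != mode for c in curves):
        raise ValueError("all replicates must share the same mode")
    conc = np.concatenate([c.concentrations for c in curves])
    resp = np.concatenate([c.responses for c in curves])
    if len(np.unique(conc)) < 4:
        raise ValueError("need at least 4 distinct concentrations for a Hill fit")
    mcmc = mcmc or HillMcmcConfig()

    logc = np.log10(conc)
    prior_center = float(np.median(logc))

    # No detectable response anywhere: the data carry no information about the
    # half-maximal concentration, so return the prior itself, flagged.
    span = float(np.max(resp) - np.min(resp))
    if span < 20.0:
        rng = np.random.default_rng(mcmc.seed)
        xc50 = 10.0 ** rng.normal(prior_center, 1.0, size=mcmc.n_draws)
        slope = np.exp(rng.normal(0.0, 0.5, size=mcmc.n_draws))
        return HillFitResult(
            xc50_draws=xc50, slope_draws=slope, uninformative=True, mode=mode
        )

    def log_prob(x):
        l10xc50, logh, low, high, lognoise = (x[..., i] for i in range(_NPAR))
        l10xc50 = np.clip(l10xc50, prior_center - 30, prior_center + 30)
        noise = np.exp(np.clip(lognoise, -10, 6))
        lp = (
            stats.norm.logpdf(l10xc50, prior_center, 1.0)
            + stats.norm.logpdf(logh, 0.0, 0.5)
            + stats.norm.logpdf(low, 0.0, 5.0)
            + stats.norm.logpdf(high, 100.0, 5.0)
            + stats.halfnorm.logpdf(noise, scale=10.0)
            + np.clip(lognoise, -10, 6)  # Jacobian of the log transform
        )
        mu = _hill_mean(x, logc, mode)
        resid = resp - mu
        ll = -0.5 * np.sum(
            (resid / noise[..., None]) ** 2, axis=-1
        ) - resid.shape[-1] * (0.5 * np.log(2 * np.pi) + np.log(noise))
        out = lp + ll
        return np.where(np.isfinite(out), out, -np.inf)

    rng = np.random.default_rng(mcmc.seed)
    init = np.column_stack(
        [
            prior_center + 0.5 * rng.standard_normal(mcmc.walkers),
            0.2 * rng.standard_normal(mcmc.walkers),
            2.0 * rng.standard_normal(mcmc.walkers),
            100.0 + 2.0 * rng.standard_normal(mcmc.walkers),
            np.log(5.0) + 0.3 * rng.standard_normal(mcmc.walkers),
        ]
    )
    sampler = emcee.EnsembleSampler(mcmc.walkers, _NPAR, log_prob, vectorize=True)
    sampler.random_state = np.random.RandomState(mcmc.seed).get_state()
    state = sampler.run_mcmc(init, mcmc.warmup, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, mcmc.samples, progress=False)
    flat = sampler.get_chain(flat=True)
    take = np.linspace(0, flat.shape[0] - 1, mcmc.n_draws).astype(int)
    flat = flat[take]

    xc50 = 10.0 ** flat[:, 0]
    slope = np.exp(flat[:, 1])
    # still prior-dominated if the posterior is nearly as wide as the prior
    uninformative = float(np.std(flat[:, 0])) > 0.8
    return HillFitResult(xc50_draws=xc50, slope_draws=slope, uninformative=uninformative, mode=mode)


# --------------------------------------------------------------------------
# minimum platform POD
# --------------------------------------------------------------------------


def min_platform_pod(
    pods: Iterable[PODRecord],
    chemical: str,
    subset: Optional[Iterable[Platform | str]] = None,
) -> float:
    """Minimum POD (µM) for a chemical over a platform subset.

    With ``subset=None`` all platforms are used, giving the workflow's
    minimum POD. Monotone in subset inclusion: enlarging the subset can only
    lower (or keep) the minimum.
    """
    if subset is not None:
        subset = {Platform(s) for s in subset}
    vals = [
        p.pod_um
        for p in pods
        if p.chemical_name == chemical and (subset is None or p.platform in subset)
    ]
    if not vals:
        raise ValueError(
            f"no POD records for chemical {chemical!r}"
            + (f" within subset {sorted(s.value for s in subset)}" if subset else "")
        )
    return float(min(vals))
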