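"""Bioactivity exposure ratios, tiered decision thresholds, protectiveness and utility.

The bioactivity exposure ratio (BER) for a scenario is B = P / C, the minimum
in vitro point of departure P (µM) over the plasma Cmax C (µM). Because the
Cmax error model is normal on the log10 scale, BER distributions are lognormal:
their geometric mean is the BER point estimate P / Cmax-estimate, and a
confidence requirement Prob(BER > 1) > p_threshold is equivalent to the point
estimate exceeding a level-specific "threshold BER". Lower PBK parameterization
levels carry more Cmax uncertainty, so consistent decision-making (low-risk
calls unlikely to be overturned when the PBK model is refined) demands larger
threshold BERs at L1 than at L3.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import optimize, special

from .data import CmaxRecord, Dataset, RiskLabel
from .errormodel import (
    LEVELS,
    PosteriorFit,
    PredictiveDistribution,
    _conditional_zeta,
    _FIELD_OF,
    level_gap_sd,
)
from .pod import min_platform_pod

__all__ = [
    "BERDistribution",
    "DecisionModel",
    "ber_distribution",
    "ber_at_level",
    "prob_ber_above",
    "threshold_from_confidence",
    "derive_consistent_thresholds",
    "decide",
    "decide_from_distribution",
    "protectiveness",
    "utility",
    "point_biserial_distribution",
    "evaluate_decisions",
]

LOW_RISK = "low_risk"
UNCERTAIN_RISK = "uncertain_risk"


class BERDistribution:
    """Monte-Carlo BER distribution B_i = P / 10^zeta_i for one scenario/level.

    Quantiles are defined through the Cmax draw set by the exact identity
    q_p(BER) * 10^(q_(1-p)(zeta)) = P, so they are order-consistent with the
    underlying Cmax quantiles by construction.
    """

    def __init__(self, scenario_key, level: Optional[str], pod_um: float, zeta_draws):
        zeta_draws = np.asarray(zeta_draws, float)
        if pod_um <= 0 or not np.isfinite(pod_um):
            raise ValueError("pod_um must be finite and > 0")
        if zeta_draws.size == 0 or not np.all(np.isfinite(zeta_draws)):
            raise ValueError("zeta draws must be nonempty and finite")
        self.scenario_key = scenario_key
        self.level = level
        self.pod_um = float(pod_um)
        self.zeta_draws = zeta_draws

    @property
    def draws(self) -> np.ndarray:
        """BER samples, positive by construction."""
        return self.pod_um / 10.0**self.zeta_draws

    @property
    def log10_draws(self) -> np.ndarray:
        return np.log10(self.pod_um) - self.zeta_draws

    @property
    def point_estimate(self) -> float:
        """Geometric mean of the BER draws, 10^mean(log10 B)."""
        return float(10.0 ** np.mean(self.log10_draws))

    @property
    def prob_gt_1(self) -> float:
        return prob_ber_above(self, 1.0)

    def quantile(self, q):
        q = np.asarray(q, float)
        out = self.pod_um / 10.0 ** np.quantile(self.zeta_draws, 1.0 - q)
        return out if out.ndim else float(out)

    def mc_se_prob_above(self, cut: float = 1.0) -> float:
        p = prob_ber_above(self, cut)
        return float(np.sqrt(p * (1 - p) / self.zeta_draws.size))


def ber_distribution(
    pod_um: float, cmax_pred: PredictiveDistribution, level: Optional[str] = None
) -> BERDistribution:
    """BER distribution from a POD and a predictive Cmax distribution."""
    return BERDistribution(cmax_pred.scenario_key, level, pod_um, cmax_pred.draws)


def ber_at_level(
    fit: PosteriorFit, record: CmaxRecord, pod_um: float, level: str
) -> BERDistribution:
    """BER distribution as seen by a risk assessor working at one PBK level.

    Conditions the population-average Cmax predictive only on PBK estimates at
    levels <= ``level`` (no clinical value, no higher levels), mirroring the
    information actually available in an ab initio assessment at that level.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}")
    if getattr(record, _FIELD_OF[level]) is None:
        raise ValueError(f"scenario {record.key} has no {level} estimate")
    keep_rank = LEVELS.index(level)
    update = {"zhat_clinical": None}
    for rank, lev in enumerate(LEVELS):
        if rank > keep_rank:
            update[_FIELD_OF[lev]] = None
    reduced = record.model_copy(update=update)
    mu, sd = _conditional_zeta(reduced, fit.params, fit.spec)
    rng = fit.rng_for("ber", "|".join(record.key), level)
    zeta = mu + sd * rng.standard_normal(mu.shape)
    return BERDistribution(record.key, level, pod_um, zeta)


def prob_ber_above(dist: BERDistribution, cut: float = 1.0) -> float:
    """Fraction of BER draws strictly above ``cut``."""
    if cut <= 0:
        raise ValueError("cut must be > 0")
    return float(np.mean(dist.log10_draws > np.log10(cut)))


def threshold_from_confidence(p: float, sd_log10: float) -> float:
    """Threshold BER equivalent to requiring Prob(BER > 1) > p.

    Under the lognormal BER property, Prob(BER > 1) > p iff the BER point
    estimate exceeds 10^(z_p * sd_log10) with z_p the standard-normal quantile.
    Strictly increasing in both arguments (for p > 0.5).
    """
    if not 0 < p < 1:
        raise ValueError("p must lie in (0, 1)")
    if sd_log10 <= 0:
        raise ValueError("sd_log10 must be > 0")
    return float(10.0 ** (special.ndtri(p) * sd_log10))


@dataclass(frozen=True)
class DecisionModel:
    """Per-level confidence thresholds and their equivalent threshold BERs."""

    p_threshold: Mapping[str, float]
    threshold_ber: Mapping[str, float]
    overturn_prob: float = 0.1

    def __post_init__(self):
        for lev, p in self.p_threshold.items():
            if not 0 < p < 1:
                raise ValueError(f"p_threshold[{lev}]={p} not in (0, 1)")
        for lev, t in self.threshold_ber.items():
            if t <= 0:
                raise ValueError(f"threshold_ber[{lev}]={t} must be > 0")


def _context_record(level: str) -> CmaxRecord:
    """A unit scenario observed only at PBK levels <= ``level`` (zhat = 0)."""
    from .data import ExposureScenario

    scen = ExposureScenario(
        chemical_name="__context__", route="oral", exposure_label=level
    )
    keep_rank = LEVELS.index(level)
    fields = {
        _FIELD_OF[lev]: 0.0 for rank, lev in enumerate(LEVELS) if rank <= keep_rank
    }
    return CmaxRecord(scenario=scen, **fields)


def _context_moments(fit: PosteriorFit) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-draw conditional moments of the population-average log10 Cmax for a
    new scenario observed only up to each level (unknown fractions -> model
    defaults). The mean deviations (driven by the posterior spread of the bias
    terms) matter: Prob(BER > 1) for a boundary scenario is an average over
    them, not a single-normal tail probability."""
    out = {}
    for lev in LEVELS:
        mu, sd = _conditional_zeta(_context_record(lev), fit.params, fit.spec)
        out[lev] = (mu - mu.mean(), sd)
    return out


def derive_consistent_thresholds(
    fit: PosteriorFit,
    top_level_p: float = 0.95,
    overturn_prob: float = 0.1,
    n_mc: int = 100_000,
) -> DecisionModel:
    """Cross-level consistent confidence thresholds and threshold BERs.

    Starting at the highest PBK level with ``p = top_level_p``, each lower
    level's threshold BER is the smallest value such that a boundary scenario
    (point estimate exactly at the threshold) loses its low-risk classification
    at the next level with probability at most ``overturn_prob``. The gap
    between adjacent-level point estimates is simulated from the joint
    generative chain using the posterior draws of (sigma, beta) and the
    unknown-fraction defaults; the equivalent p_threshold at each level is the
    boundary scenario's Prob(BER > 1), averaged over the posterior.
    """
    if not (0 < top_level_p < 1 and 0 < overturn_prob < 1):
        raise ValueError("probabilities must lie in (0, 1)")
    moments = _context_moments(fit)
    rng = fit.rng_for("thresholds")

    def boundary_confidence(log10_t: float, level: str) -> float:
        dev, sd = moments[level]
        return float(np.mean(special.ndtr((log10_t - dev) / sd)))

    def solve_log10_t(target_p: float, level: str) -> float:
        return optimize.brentq(
            lambda x: boundary_confidence(x, level) - target_p, -15.0, 15.0, xtol=1e-10
        )

    log10_t = {"L3": solve_log10_t(top_level_p, "L3")}
    p_thr = {"L3": top_level_p}

    sig = fit.param_array("sigma")
    bet = fit.param_array("beta")
    gap_f = {"L2": fit.spec.default_f_L2L3, "L1": fit.spec.default_f_L1L2}
    for lower, upper in (("L2", "L3"), ("L1", "L2")):
        gap_sd = level_gap_sd(sig, bet, gap_f[lower])
        idx = rng.integers(0, gap_sd.size, n_mc)
        eps = gap_sd[idx] * rng.standard_normal(n_mc)
        # smallest boundary point estimate keeping
        # P(point estimate at next level <= next threshold) <= overturn_prob
        log10_t[lower] = float(log10_t[upper] - np.quantile(eps, overturn_prob))
        p = boundary_confidence(log10_t[lower], lower)
        if not 0 < p < 1 or not np.isfinite(log10_t[lower]):
            raise ValueError(f"consistency constraint unattainable at level {lower}")
        p_thr[lower] = p

    return DecisionModel(
        p_threshold={lev: p_thr[lev] for lev in LEVELS},
        threshold_ber={lev: float(10.0 ** log10_t[lev]) for lev in LEVELS},
        overturn_prob=overturn_prob,
    )


def decide(point_estimate: float, level: str, model: DecisionModel) -> str:
    """Low risk iff the BER point estimate strictly exceeds the level's threshold BER."""
    if level not in model.threshold_ber:
        raise ValueError(f"no threshold for level {level!r}")
    if point_estimate <= 0:
        raise ValueError("point_estimate must be > 0")
    return LOW_RISK if point_estimate > model.threshold_ber[level] else UNCERTAIN_RISK


def decide_from_distribution(dist: BERDistribution, level: str, model: DecisionModel) -> str:
    """Low risk iff Prob(BER > 1) strictly exceeds the level's confidence threshold."""
    if level not in model.p_threshold:
        raise ValueError(f"no confidence threshold for level {level!r}")
    return LOW_RISK if prob_ber_above(dist, 1.0) > model.p_threshold[level] else UNCERTAIN_RISK


def protectiveness(decisions: Mapping, labels: Mapping) -> float:
    """Proportion of high-risk scenarios NOT classified low risk."""
    high = [k for k, lab in labels.items() if RiskLabel(lab) == RiskLabel.high]
    if not high:
        raise ValueError("no high-risk scenarios in the label set")
    return sum(decisions[k] != LOW_RISK for k in high) / len(high)


def utility(decisions: Mapping, labels: Mapping) -> float:
    """Proportion of low-risk scenarios correctly classified low risk."""
    low = [k for k, lab in labels.items() if RiskLabel(lab) == RiskLabel.low]
    if not low:
        raise ValueError("no low-risk scenarios in the label set")
    return sum(decisions[k] == LOW_RISK for k in low) / len(low)


def point_biserial_distribution(
    fit: PosteriorFit, ds: Dataset, pods=None
) -> dict:
    """Posterior distribution of the point-biserial correlation between log10 BER
    and the binary benchmark risk label (high = 1) across labelled scenarios.

    One correlation per posterior draw, using that draw's latent true log10
    Cmax for every scenario; returns the mean and central 95% interval.
    """
    pods = ds.pods if pods is None else list(pods)
    keys, y, cols = [], [], []
    for rec in ds.scenarios:
        lab = rec.scenario.risk_label
        if lab == RiskLabel.unlabelled:
            continue
        col = f"zeta[{'|'.join(rec.key)}]"
        if col not in fit.draws.columns:
            raise ValueError(f"scenario {rec.key} absent from the fitted posterior")
        pod = min_platform_pod(pods, rec.scenario.chemical_name)
        keys.append(rec.key)
        y.append(1.0 if lab == RiskLabel.high else 0.0)
        cols.append(np.log10(pod) - fit.draws[col].to_numpy())
    y = np.asarray(y)
    if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 scenarios per risk label")
    x = np.column_stack(cols)  # (S, n)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(sx > 0, (xc @ yc) / (sx * sy), 0.0)
    lo, hi = np.quantile(r, [0.025, 0.975])
    return {
        "mean": float(r.mean()),
        "interval_95": (float(lo), float(hi)),
        "draws": r,
        "n_scenarios": len(keys),
    }


def evaluate_decisions(
    fit: PosteriorFit,
    ds: Dataset,
    model: DecisionModel,
    levels: Iterable[str] = LEVELS,
) -> dict:
    """Apply the decision model to every labelled scenario at each PBK level.

    Returns per level: the decisions map, utility and protectiveness, plus a
    per-scenario table of Prob(BER > 1), quantiles and point estimates.
    """
    out: dict = {}
    for lev in levels:
        decisions, labels, rows = {}, {}, []
        for rec in ds.scenarios:
            if rec.scenario.risk_label == RiskLabel.unlabelled:
                continue
            if getattr(rec, _FIELD_OF[lev]) is None:
                continue
            pod = min_platform_pod(ds.pods, rec.scenario.chemical_name)
            dist = ber_at_level(fit, rec, pod, lev)
            d = decide(dist.point_estimate, lev, model)
            decisions[rec.key] = d
            labels[rec.key] = rec.scenario.risk_label.value
            q = dist.quantile(np.array([0.025, 0.5, 0.975]))
            rows.append(
                {
                    "chemical": rec.scenario.chemical_name,
                    "route": rec.scenario.route.value,
                    "exposure_label": rec.scenario.exposure_label,
                    "level": lev,
                    "risk_label": labels[rec.key],
                    "prob_ber_gt1": prob_ber_above(dist, 1.0),
                    "ber_q2.5": q[0],
                    "ber_q50": q[1],
                    "ber_q97.5": q[2],
                    "point_estimate": dist.point_estimate,
                    "decision": d,
                }
            )
        out[lev] = {
            "decisions": decisions,
            "utility": utility(decisions, labels),
            "protectiveness": protectiveness(decisions, labels),
            "table": rows,
        }
    return out
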