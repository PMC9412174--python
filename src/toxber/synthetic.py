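"""Synthetic scenario portfolios and concentration-response curves with known truth.

The portfolio generator draws from exactly the same generative chain the error
model fits (true zeta -> L3 -> L2 -> L1, plus small-noise clinical measurements),
so simulation-based calibration and full-loop recovery checks are possible
without any external data. Defaults mimic the shape of a realistic benchmark
study: 30 chemical-exposure scenarios spanning log10 Cmax from -3 to 4
(0.004-4000 µM), roughly 11 of 30 with a clinical measurement, 6 of 30 missing
the L3 estimate, and one minimum POD per chemical spanning nanomolar to
millimolar potency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CmaxRecord, Dataset, ExposureScenario, PODRecord, Platform
from .errormodel import level_gap_sd

__all__ = [
    "DEFAULT_TRUE_PARAMS",
    "SyntheticConfig",
    "generate_portfolio",
    "generate_hill_curves",
    "dilution_series",
    "hill_response",
]

DEFAULT_TRUE_PARAMS = {
    "sigma_clinical": 0.07,
    "alpha_L1": 0.2,
    "alpha_L2": 0.15,
    "alpha_L3": 0.1,
    "sigma_L3pop": 0.3,
    "sigma": 0.6,
    "beta": 0.3,
}

_ROUTES = ("oral", "dermal", "intravenous")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic benchmark portfolio.

    ``f_L2L3_range`` defaults to (0.05, 0.38): at most 38% of PBK parameters
    change between L2 and L3 in practice. ``f_L1L2_range`` defaults to
    (0.5, 1.0): a larger share of parameters changes between L1 and L2.
    Risk labels are assigned from the true BER: high risk iff
    POD / 10^zeta < ``risk_rule``.
    """

    n_scenarios: int = 30
    true_params: dict = field(default_factory=lambda: dict(DEFAULT_TRUE_PARAMS))
    zeta_range: tuple[float, float] = (-3.0, 4.0)
    f_L2L3_range: tuple[float, float] = (0.05, 0.38)
    f_L1L2_range: tuple[float, float] = (0.5, 1.0)
    fraction_with_measurement: float = 11 / 30
    fraction_missing_L3: float = 6 / 30
    pod_log10_range: tuple[float, float] = (-3.0, 3.0)
    risk_rule: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_scenarios < 0:
            raise ValueError("n_scenarios must be >= 0")
        for name in ("fraction_with_measurement", "fraction_missing_L3"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} not in [0, 1]")
        for name in ("sigma_clinical", "sigma_L3pop", "sigma", "beta"):
            if self.true_params[name] < 0:
                raise ValueError(f"true_params[{name!r}] must be >= 0")


def generate_portfolio(cfg: SyntheticConfig) -> tuple[Dataset, pd.DataFrame]:
    """Draw a portfolio from the generative model.

    Returns the Dataset (scenarios + one POD per chemical) and a truth table
    with one row per scenario: true zeta, per-gap f values, true BER, and the
    generating parameters. Deterministic for a fixed config (same seed gives
    byte-identical output).
    """
    rng = np.random.default_rng(cfg.seed)
    p = cfg.true_params
    n = cfg.n_scenarios

    zeta = rng.uniform(*cfg.zeta_range, size=n)
    f23 = rng.uniform(*cfg.f_L2L3_range, size=n)
    f12 = rng.uniform(*cfg.f_L1L2_range, size=n)
    zhat_clin = zeta + p["sigma_clinical"] * rng.standard_normal(n)
    zhat_L3 = zeta + p["alpha_L3"] + p["sigma_L3pop"] * rng.standard_normal(n)
    zhat_L2 = zhat_L3 + p["alpha_L2"] + level_gap_sd(
        p["sigma"], p["beta"], f23
    ) * rng.standard_normal(n)
    zhat_L1 = zhat_L2 + p["alpha_L1"] + level_gap_sd(
        p["sigma"], p["beta"], f12
    ) * rng.standard_normal(n)
    has_meas = rng.random(n) < cfg.fraction_with_measurement
    miss_L3 = rng.random(n) < cfg.fraction_missing_L3
    pod_log10 = rng.uniform(*cfg.pod_log10_range, size=n)

    records, pods, rows = [], [], []
    for i in range(n):
        chem = f"chem-{i:03d}"
        scenario = ExposureScenario(
            chemical_name=chem,
            route=_ROUTES[i % len(_ROUTES)],
            exposure_label=f"synthetic exposure {i:03d}",
            risk_label="high" if pod_log10[i] - zeta[i] < np.log10(cfg.risk_rule) else "low",
        )
        records.append(
            CmaxRecord(
                scenario=scenario,
                zhat_L1=float(zhat_L1[i]),
                zhat_L2=float(zhat_L2[i]),
                zhat_L3=None if miss_L3[i] else float(zhat_L3[i]),
                zhat_clinical=float(zhat_clin[i]) if has_meas[i] else None,
                f_L2L3=float(f23[i]),
                f_L1L2=float(f12[i]),
            )
        )
        pods.append(
            PODRecord(chemical_name=chem, platform=Platform.IPP, pod_um=float(10.0 ** pod_log10[i]))
        )
        rows.append(
            {
                "chemical": chem,
                "route": scenario.route.value,
                "exposure_label": scenario.exposure_label,
                "risk_label": scenario.risk_label.value,
                "zeta": zeta[i],
                "f_L2L3": f23[i],
                "f_L1L2": f12[i],
                "pod_uM": 10.0 ** pod_log10[i],
                "true_ber": 10.0 ** (pod_log10[i] - zeta[i]),
                "has_measurement": bool(has_meas[i]),
                "missing_L3": bool(miss_L3[i]),
                **{f"true_{k}": v for k, v in p.items()},
            }
        )
    truth = pd.DataFrame(rows)
    return Dataset(scenarios=records, pods=pods), truth


# --------------------------------------------------------------------------
# concentration-response fixtures
# --------------------------------------------------------------------------


def hill_response(
    conc_um, xc50_um: float, slope: float = 1.0, low: float = 0.0, high: float = 100.0,
    mode: str = "agonist",
):
    """Hill curve in % response; decreasing form for ``mode='antagonist'``."""
    c = np.asarray(conc_um, float)
    frac = c**slope / (xc50_um**slope + c**slope)
    if mode == "antagonist":
        frac = 1.0 - frac
    return low + (high - low) * frac


def dilution_series(max_conc_um: float, n: int = 8, decades: float = 4.0) -> np.ndarray:
    """Log-spaced series spanning ~4 orders of magnitude below the top concentration."""
    return np.logspace(np.log10(max_conc_um) - decades, np.log10(max_conc_um), n)


def generate_hill_curves(
    truth: dict,
    design: dict | None = None,
    seed: int = 0,
):
    """Noisy replicate concentration-response curves from a known Hill truth.

    ``truth``: {"xc50_um": µM, "slope": float, "mode": "agonist"|"antagonist"}.
    ``design`` defaults to 8 concentrations x 2 technical replicates with 5%
    observation noise, concentrations spanning 4 decades around the true xc50.
    Returns a list of ConcentrationResponse objects (one per replicate).
    """
    from .pod import ConcentrationResponse

    design = design or {}
    mode = truth.get("mode", "antagonist")
    conc = np.asarray(
        design.get(
            "concentrations",
            dilution_series(truth["xc50_um"] * 100.0, n=8, decades=4.0),
        ),
        float,
    )
    replicates = int(design.get("replicates", 2))
    noise_sd = float(design.get("noise_sd", 5.0))
    rng = np.random.default_rng(seed)
    curves = []
    for rep in range(replicates):
        clean = hill_response(
            conc,
            truth["xc50_um"],
            truth.get("slope", 1.0),
            truth.get("low", 0.0),
            truth.get("high", 100.0),
            mode=mode,
        )
        noisy = clean + noise_sd * rng.standard_normal(conc.shape)
        curves.append(
            ConcentrationResponse(
                concentrations=conc, responses=noisy, mode=mode, replicate_id=rep
            )
        )
    return curves
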