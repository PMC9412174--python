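"""End-to-end orchestration: fit -> calibrate -> BER -> decide -> evaluate.

A RunConfig (YAML-serializable, versioned, unknown keys rejected) drives the
whole workflow and every output artifact records the config hash and seed that
produced it. Any stage failure aborts with the stage name; partial outputs are
retained next to a FAILED marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .ber import derive_consistent_thresholds, evaluate_decisions
from .calibration import coverage, exceedance_stats, run_loo
from .data import Dataset, load_dataset
from .errormodel import LEVELS, McmcConfig, ModelSpec, fit_error_model

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("toxber")

CONFIG_VERSION = 1


class McmcSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chains: int = 4
    warmup: int = 1000
    samples: int = 1000
    seed: int = 1234


class DecisionSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    top_level_p: float = 0.95
    overturn_prob: float = 0.1


class RunConfig(BaseModel):
    """Serializable configuration for one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    config_version: int = CONFIG_VERSION
    scenarios: str
    pods: str
    out_dir: str
    mcmc: McmcSettings = McmcSettings()
    decision: DecisionSettings = DecisionSettings()
    platform_subset: Optional[list[str]] = None
    run_loo: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("config_version", CONFIG_VERSION) != CONFIG_VERSION:
            raise ValueError(f"unsupported config_version {raw.get('config_version')}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]


def _stage(name: str, out: Path, fn, *args, **kwargs):
    t0 = time.time()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {name}\ncause: {exc}\n")
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    logger.info("stage %s done in %.1fs", name, time.time() - t0)
    return result


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow; returns the evaluation summary dict."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mcmc = McmcConfig(**cfg.mcmc.model_dump())
    spec = ModelSpec()

    ds: Dataset = _stage("load", out, load_dataset, cfg.scenarios, cfg.pods)
    if cfg.platform_subset:
        allowed = set(cfg.platform_subset)
        ds = Dataset(
            scenarios=ds.scenarios,
            pods=[p for p in ds.pods if p.platform.value in allowed],
        )

    fit = _stage("fit", out, fit_error_model, ds, spec, mcmc)
    fit.save(out / "posterior")

    calib = None
    if cfg.run_loo:
        loo = _stage("calibrate", out, run_loo, ds, spec, mcmc)
        rows = []
        for e in loo.entries:
            q = [e.predictive.quantile(p) for p in (0.025, 0.25, 0.5, 0.75, 0.975)]
            rows.append(
                {
                    "chemical": e.scenario_key[0],
                    "route": e.scenario_key[1],
                    "exposure_label": e.scenario_key[2],
                    "level": e.level_context,
                    "q2.5": q[0], "q25": q[1], "q50": q[2], "q75": q[3], "q97.5": q[4],
                    "measured": e.measured,
                    "fold95": 10.0 ** (e.predictive.quantile(0.95) - e.measured),
                }
            )
        pd.DataFrame(rows).to_csv(out / "calibration.csv", index=False)
        calib = {
            "coverage_95": coverage(loo, 0.95),
            "coverage_50": coverage(loo, 0.50),
            "exceedance": {
                lev: exceedance_stats(loo, lev) for lev in LEVELS if loo.at_level(lev)
            },
        }

    model = _stage(
        "thresholds",
        out,
        derive_consistent_thresholds,
        fit,
        cfg.decision.top_level_p,
        cfg.decision.overturn_prob,
    )
    evaluation = _stage("decide", out, evaluate_decisions, fit, ds, model)

    table = [row for lev in evaluation for row in evaluation[lev]["table"]]
    pd.DataFrame(table).to_csv(out / "decisions.csv", index=False)

    summary = {
        "decision_model": {
            "p_threshold": dict(model.p_threshold),
            "threshold_ber": dict(model.threshold_ber),
            "overturn_prob": model.overturn_prob,
        },
        "per_level": {
            lev: {
                "utility": evaluation[lev]["utility"],
                "protectiveness": evaluation[lev]["protectiveness"],
            }
            for lev in evaluation
        },
        "calibration": calib,
        "converged": fit.converged,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))

    manifest = {
        "config": cfg.model_dump(),
        "config_hash": cfg.digest(),
        "seed": cfg.mcmc.seed,
        "software": {"toxber": __version__},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
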