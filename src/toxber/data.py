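"""Domain types, validation and file I/O for exposure scenarios, Cmax observations and PODs.

All concentrations are micromolar (µM). Cmax values are stored internally as their
base-10 logarithm (``zhat_*`` fields, log10 µM); loaders convert natural-scale µM
columns on the way in and writers convert back on the way out. Fractions of PBK
parameters changed between adjacent parameterization levels may be unknown, encoded
as ``None`` in memory and as an empty cell or the token ``"unknown"`` on disk;
substitution of the model defaults happens at fit time, never at load time.
"""

from __future__ import annotations

import json
import math
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "Route",
    "RiskLabel",
    "Platform",
    "ExposureScenario",
    "CmaxRecord",
    "PODRecord",
    "Dataset",
    "ValidationError",
    "load_dataset",
    "save_dataset",
    "UNKNOWN_TOKEN",
]

UNKNOWN_TOKEN = "unknown"

SCENARIO_COLUMNS = [
    "chemical",
    "route",
    "exposure_label",
    "risk_label",
    "cmax_L1_uM",
    "cmax_L2_uM",
    "cmax_L3_uM",
    "cmax_measured_uM",
    "f_L2L3",
    "f_L1L2",
]
POD_COLUMNS = ["chemical", "platform", "pod_uM"]


class ValidationError(ValueError):
    """Schema or invariant violation, with a machine-readable error code."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


class Route(str, Enum):
    oral = "oral"
    dermal = "dermal"
    intravenous = "intravenous"


class RiskLabel(str, Enum):
    low = "low"
    high = "high"
    unlabelled = "unlabelled"


#: Closed vocabulary of bioactivity platforms: in vitro pharmacological profiling,
#: the cell stress panel (BIFROST global POD), and high-throughput transcriptomics
#: per cell line analysed either with BIFROST or with pathway-level BMDLs.
_HTTR_CELLS = ("HepG2", "HepaRG", "MCF7")
Platform = Enum(
    "Platform",
    {
        "IPP": "IPP",
        "CSP_BIFROST": "CSP_BIFROST",
        **{f"HTTr_{c}_BIFROST": f"HTTr_{c}_BIFROST" for c in _HTTR_CELLS},
        **{f"HTTr_{c}_BMDL": f"HTTr_{c}_BMDL" for c in _HTTR_CELLS},
    },
    type=str,
)


class ExposureScenario(BaseModel):
    """A chemical-exposure scenario with its benchmark risk classification."""

    model_config = ConfigDict(frozen=True)

    chemical_name: str
    route: Route
    exposure_label: str
    risk_label: RiskLabel = RiskLabel.unlabelled

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.chemical_name, self.route.value, self.exposure_label)


def _check_fraction(v, name: str):
    if v is None:
        return None
    v = float(v)
    if not math.isfinite(v) or not (0.0 <= v <= 1.0):
        raise ValidationError("fraction_out_of_range", f"{name}={v} not in [0, 1]")
    return v


class CmaxRecord(BaseModel):
    """Level-wise log10 Cmax observations for one exposure scenario.

    ``zhat_*`` fields are log10(µM); ``f_L2L3`` / ``f_L1L2`` are the fractions of
    PBK parameters whose values differ between the adjacent levels (``None`` if
    unknown).
    """

    model_config = ConfigDict(frozen=True)

    scenario: ExposureScenario
    zhat_L1: Optional[float] = None
    zhat_L2: Optional[float] = None
    zhat_L3: Optional[float] = None
    zhat_clinical: Optional[float] = None
    f_L2L3: Optional[float] = None
    f_L1L2: Optional[float] = None

    @field_validator("zhat_L1", "zhat_L2", "zhat_L3", "zhat_clinical")
    @classmethod
    def _finite(cls, v, info):
        if v is not None and not math.isfinite(v):
            raise ValidationError("nonfinite_cmax", f"{info.field_name}={v} is not finite")
        return v

    @field_validator("f_L2L3", "f_L1L2")
    @classmethod
    def _frac(cls, v, info):
        return _check_fraction(v, info.field_name)

    @model_validator(mode="after")
    def _at_least_one_observation(self):
        if all(
            getattr(self, f) is None
            for f in ("zhat_L1", "zhat_L2", "zhat_L3", "zhat_clinical")
        ):
            raise ValidationError(
                "no_observations",
                f"scenario {self.scenario.key} has no Cmax observation at any level",
            )
        return self

    @property
    def key(self) -> tuple[str, str, str]:
        return self.scenario.key

    def observed_levels(self) -> list[str]:
        """Names of the observed components, in chain order."""
        return [
            name
            for name, field in (
                ("clinical", "zhat_clinical"),
                ("L3", "zhat_L3"),
                ("L2", "zhat_L2"),
                ("L1", "zhat_L1"),
            )
            if getattr(self, field) is not None
        ]


class PODRecord(BaseModel):
    """One point of departure (µM) for a chemical on one bioactivity platform."""

    model_config = ConfigDict(frozen=True)

    chemical_name: str
    platform: Platform
    pod_um: float

    @field_validator("pod_um")
    @classmethod
    def _positive(cls, v):
        if not math.isfinite(v) or v <= 0:
            raise ValidationError("nonpositive_pod", f"pod_um={v} must be finite and > 0")
        return v


class Dataset(BaseModel):
    """Aggregate container: Cmax scenario records plus platform POD records."""

    scenarios: list[CmaxRecord] = []
    pods: list[PODRecord] = []

    @model_validator(mode="after")
    def _unique_scenarios(self):
        keys = [r.key for r in self.scenarios]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValidationError(
                "duplicate_scenario",
                f"(chemical, route, exposure_label) not unique: {dupes}",
            )
        return self

    def __len__(self) -> int:
        return len(self.scenarios)

    def record(self, key: tuple[str, str, str]) -> CmaxRecord:
        for r in self.scenarios:
            if r.key == key:
                return r
        raise KeyError(key)

    def pods_for(self, chemical: str) -> list[PODRecord]:
        return [p for p in self.pods if p.chemical_name == chemical]

    # ---- tabular views -------------------------------------------------

    def scenarios_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.scenarios:
            rows.append(
                {
                    "chemical": r.scenario.chemical_name,
                    "route": r.scenario.route.value,
                    "exposure_label": r.scenario.exposure_label,
                    "risk_label": r.scenario.risk_label.value,
                    "cmax_L1_uM": _to_um(r.zhat_L1),
                    "cmax_L2_uM": _to_um(r.zhat_L2),
                    "cmax_L3_uM": _to_um(r.zhat_L3),
                    "cmax_measured_uM": _to_um(r.zhat_clinical),
                    "f_L2L3": UNKNOWN_TOKEN if r.f_L2L3 is None else r.f_L2L3,
                    "f_L1L2": UNKNOWN_TOKEN if r.f_L1L2 is None else r.f_L1L2,
                }
            )
        return pd.DataFrame(rows, columns=SCENARIO_COLUMNS)

    def pods_frame(self) -> pd.DataFrame:
        rows = [
            {"chemical": p.chemical_name, "platform": p.platform.value, "pod_uM": p.pod_um}
            for p in self.pods
        ]
        return pd.DataFrame(rows, columns=POD_COLUMNS)

    def to_json(self) -> str:
        return json.dumps(
            {
                "scenarios": json.loads(self.scenarios_frame().to_json(orient="records")),
                "pods": json.loads(self.pods_frame().to_json(orient="records")),
            },
            indent=2,
        )


def _to_um(zhat: Optional[float]) -> Optional[float]:
    return None if zhat is None else 10.0**zhat


def _parse_cmax(value, row: int, column: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            "bad_number", f"row {row}, column {column!r}: {value!r} is not a number"
        ) from None
    if not math.isfinite(x) or x <= 0:
        raise ValidationError(
            "nonpositive_concentration",
            f"row {row}, column {column!r}: concentration {x} must be > 0 µM",
        )
    return math.log10(x)


def _parse_fraction(value, row: int, column: str) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        s = value.strip().lower()
        if s in ("", UNKNOWN_TOKEN):
            return None
        value = s
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ValidationError(
            "bad_number", f"row {row}, column {column!r}: {value!r} is not a fraction"
        ) from None
    if not (0.0 <= x <= 1.0):
        raise ValidationError(
            "fraction_out_of_range", f"row {row}, column {column!r}: {x} not in [0, 1]"
        )
    return x


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError("missing_columns", f"{path}: missing columns {missing}")


def load_dataset(scenario_path, pod_path=None) -> Dataset:
    """Load and validate a Dataset from the documented CSV schemas.

    Natural-scale µM Cmax columns are converted to base-10 logarithms; empty or
    ``"unknown"`` fraction cells are parsed as unknown. Errors name the offending
    row and column.
    """
    scen_df = pd.read_csv(scenario_path)
    _require_columns(scen_df, SCENARIO_COLUMNS, scenario_path)
    records = []
    for i, row in scen_df.iterrows():
        try:
            scenario = ExposureScenario(
                chemical_name=str(row["chemical"]),
                route=row["route"],
                exposure_label=str(row["exposure_label"]),
                risk_label=row["risk_label"] if pd.notna(row["risk_label"]) else "unlabelled",
            )
            records.append(
                CmaxRecord(
                    scenario=scenario,
                    zhat_L1=_parse_cmax(row["cmax_L1_uM"], i, "cmax_L1_uM"),
                    zhat_L2=_parse_cmax(row["cmax_L2_uM"], i, "cmax_L2_uM"),
                    zhat_L3=_parse_cmax(row["cmax_L3_uM"], i, "cmax_L3_uM"),
                    zhat_clinical=_parse_cmax(row["cmax_measured_uM"], i, "cmax_measured_uM"),
                    f_L2L3=_parse_fraction(row["f_L2L3"], i, "f_L2L3"),
                    f_L1L2=_parse_fraction(row["f_L1L2"], i, "f_L1L2"),
                )
            )
        except ValidationError:
            raise
        except (ValueError, TypeError) as exc:
            raise ValidationError("bad_row", f"{scenario_path} row {i}: {exc}") from exc

    pods: list[PODRecord] = []
    if pod_path is not None:
        pod_df = pd.read_csv(pod_path)
        _require_columns(pod_df, POD_COLUMNS, pod_path)
        for i, row in pod_df.iterrows():
            pod = row["pod_uM"]
            if pd.isna(pod) or float(pod) <= 0:
                raise ValidationError(
                    "nonpositive_pod", f"{pod_path} row {i}, column 'pod_uM': {pod}"
                )
            try:
                pods.append(
                    PODRecord(
                        chemical_name=str(row["chemical"]),
                        platform=row["platform"],
                        pod_um=float(pod),
                    )
                )
            except ValueError as exc:
                raise ValidationError("bad_row", f"{pod_path} row {i}: {exc}") from exc

    return Dataset(scenarios=records, pods=pods)


def save_dataset(ds: Dataset, out_dir) -> tuple[Path, Path]:
    """Write ``scenarios.csv`` and ``pods.csv``; round-trips through load_dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scen_path = out / "scenarios.csv"
    pod_path = out / "pods.csv"
    # repr-precision floats so the round trip is exact to double precision
    ds.scenarios_frame().to_csv(scen_path, index=False, float_format="%.17g")
    ds.pods_frame().to_csv(pod_path, index=False, float_format="%.17g")
    return scen_path, pod_path
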