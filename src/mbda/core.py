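"""Domain types, marker transforms, coefficient configuration and tabular I/O.

All downstream stages consume the types defined here: :class:`PatientRecord`
rows collected into a :class:`Cohort`, and :class:`AlgorithmCoefficients`
holding every constant of the scoring algorithm as swappable configuration.
The scoring code never hard-codes model constants; they are transcribed into
a default YAML file shipped with the package and loaded at run time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PANEL_ANALYTES",
    "COMPONENT_NAMES",
    "SchemaError",
    "ConfigError",
    "DomainError",
    "MarkerConcentration",
    "PatientRecord",
    "ComponentModel",
    "AlgorithmCoefficients",
    "Cohort",
    "RowRejection",
    "transform_concentration",
    "load_cohort",
    "write_cohort",
    "cohort_from_frame",
    "load_coefficients",
    "default_coefficients",
]

#: The 12-analyte panel of the final algorithm. CRP enters the combination
#: equation directly (in mg/L); the other 11 feed the component models (pg/mL).
PANEL_ANALYTES: tuple[str, ...] = (
    "TNFRI",
    "IL6",
    "VCAM1",
    "EGF",
    "VEGFA",
    "YKL40",
    "MMP1",
    "MMP3",
    "SAA",
    "LEPTIN",
    "RESISTIN",
    "CRP",
)

#: Components predicted from serum markers (CRP is measured, not predicted).
COMPONENT_NAMES: tuple[str, ...] = ("PTJC28", "PSJC28", "PPGA")

_CLINICAL_COLUMNS = (
    "patient_id",
    "visit_id",
    "tjc28",
    "sjc28",
    "pga",
    "crp_mg_l",
    "esr_mm_h",
    "age",
    "sex",
    "rf_status",
    "ccp_status",
)

_REQUIRED_COLUMNS = ("patient_id", "tjc28", "sjc28", "pga", "crp_mg_l")

_DEFAULT_COEFFS_PATH = Path(__file__).parent / "data" / "default_coefficients.yaml"


class SchemaError(ValueError):
    """A cohort table is missing required columns or is otherwise malformed."""


class ConfigError(ValueError):
    """A coefficients configuration file is invalid."""


class DomainError(ValueError):
    """An input value lies outside its mathematical domain."""


def transform_concentration(value: float, exponent: float, analyte: str | None = None) -> float:
    """Power-transform a non-negative concentration (default exponent 0.1).

    Parameters
    ----------
    value
        Concentration, must be >= 0.
    exponent
        Power to raise the concentration to; the scoring default is 0.1,
        which maps skewed marker distributions toward normality.
    analyte
        Optional analyte name used only to label the error message.

    Returns
    -------
    float
        ``value ** exponent``; monotone non-decreasing in ``value``.
    """
    if value < 0:
        label = f" for analyte {analyte!r}" if analyte else ""
        raise DomainError(f"negative concentration {value!r}{label}")
    return float(value) ** exponent


@dataclass(frozen=True)
class MarkerConcentration:
    """A single analyte measurement on one patient-visit.

    ``units`` defaults to pg/mL; CRP is carried in mg/L throughout.
    """

    analyte_id: str
    value: float
    units: str = "pg/mL"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise DomainError(
                f"negative concentration {self.value!r} for analyte {self.analyte_id!r}"
            )


@dataclass
class PatientRecord:
    """One patient-visit: marker concentrations, clinical measures, covariates."""

    patient_id: str
    visit_id: str = "1"
    markers: dict[str, MarkerConcentration] = field(default_factory=dict)
    tjc28: int = 0
    sjc28: int = 0
    pga: float = 0.0  # 0-10 scale
    crp_mg_l: float = 0.0
    esr_mm_h: float | None = None
    age: float | None = None
    sex: str | None = None
    rf_status: bool | None = None
    ccp_status: bool | None = None
    therapy: dict[str, bool] = field(default_factory=dict)
    comorbidities: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.tjc28 <= 28:
            raise DomainError(f"tjc28={self.tjc28} outside [0, 28]")
        if not 0 <= self.sjc28 <= 28:
            raise DomainError(f"sjc28={self.sjc28} outside [0, 28]")
        if not 0 <= self.pga <= 10:
            raise DomainError(f"pga={self.pga} outside [0, 10]")
        if self.crp_mg_l < 0:
            raise DomainError(f"crp_mg_l={self.crp_mg_l} negative")

    def marker_value(self, analyte_id: str) -> float:
        """Concentration of ``analyte_id``; CRP falls back to ``crp_mg_l``."""
        if analyte_id in self.markers:
            return self.markers[analyte_id].value
        if analyte_id == "CRP":
            return self.crp_mg_l
        raise KeyError(analyte_id)


@dataclass(frozen=True)
class ComponentModel:
    """Linear model for one predicted component: intercept + sum(w * x^exponent)."""

    intercept: float
    coefficients: Mapping[str, float]

    def predict(self, record: PatientRecord, exponent: float) -> float:
        total = self.intercept
        for analyte, weight in self.coefficients.items():
            try:
                conc = record.marker_value(analyte)
            except KeyError:
                raise ScoringInputError(
                    f"record {record.patient_id!r} missing analyte {analyte!r}"
                ) from None
            total += weight * transform_concentration(conc, exponent, analyte)
        return total


class ScoringInputError(ValueError):
    """A record lacks an analyte required by the configured models."""


@dataclass(frozen=True)
class AlgorithmCoefficients:
    """Every constant of the scoring algorithm, as configuration.

    Attributes
    ----------
    components
        Map ``PTJC28``/``PSJC28``/``PPGA`` -> :class:`ComponentModel`.
    shrinkage
        2x2 matrix applied to (PTJC28, PSJC28); predicted PGA and CRP are
        deliberately excluded from shrinkage.
    combination
        Weights of the DAS28-CRP-analogous combination:
        ``w_tjc*sqrt(IPTJC) + w_sjc*sqrt(ISJC) + w_crp*ln(CRP+1) +
        w_pga*PPGA + constant``.
    scale, offset
        Final integer score = clamp(round(pre_scale*scale + offset), lo, hi).
    exponent
        Concentration power transform used inside component models.
    crp_unit
        Unit the combination's CRP log-term expects ("mg/L").
    """

    components: Mapping[str, ComponentModel]
    shrinkage: tuple[tuple[float, float], tuple[float, float]]
    combination: Mapping[str, float]
    scale: float = 10.53
    offset: float = 1.0
    score_min: int = 1
    score_max: int = 100
    exponent: float = 0.1
    crp_unit: str = "mg/L"
    panel: tuple[str, ...] = PANEL_ANALYTES

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ConfigError("scale factor must be > 0")
        if not self.score_min < self.score_max:
            raise ConfigError("score bounds must satisfy low < high")
        missing = set(COMPONENT_NAMES) - set(self.components)
        if missing:
            raise ConfigError(f"missing component models: {sorted(missing)}")
        for name, model in self.components.items():
            unknown = set(model.coefficients) - set(self.panel)
            if unknown:
                raise ConfigError(
                    f"component {name}: analytes not in panel: {sorted(unknown)}"
                )
        for key in ("w_tjc", "w_sjc", "w_crp", "w_pga", "constant"):
            if key not in self.combination:
                raise ConfigError(f"combination missing weight {key!r}")

    @property
    def shrinkage_matrix(self) -> np.ndarray:
        return np.asarray(self.shrinkage, dtype=float)


@dataclass
class RowRejection:
    """Diagnostic for a cohort row that failed validation on load."""

    row_index: int
    reason: str
    detail: str


@dataclass
class Cohort:
    """Ordered sequence of patient records plus study metadata."""

    records: list[PatientRecord] = field(default_factory=list)
    metadata: dict[str, Any] = field(default_factory=dict)
    rejections: list[RowRejection] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(r.patient_id, r.visit_id) for r in self.records]
        if len(keys) != len(set(keys)):
            raise SchemaError("duplicate (patient_id, visit_id) pairs in cohort")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.records[i]

    @property
    def analytes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            for a in rec.markers:
                seen.setdefault(a)
        return list(seen)

    def marker_matrix(self, analytes: Sequence[str] | None = None) -> pd.DataFrame:
        """Marker concentrations as a (records x analytes) frame; NaN if absent."""
        analytes = list(analytes) if analytes is not None else self.analytes
        rows = []
        for rec in self.records:
            row = {}
            for a in analytes:
                try:
                    row[a] = rec.marker_value(a)
                except KeyError:
                    row[a] = np.nan
            rows.append(row)
        idx = pd.MultiIndex.from_tuples(
            [(r.patient_id, r.visit_id) for r in self.records],
            names=["patient_id", "visit_id"],
        )
        return pd.DataFrame(rows, index=idx, columns=analytes)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical one-row-per-visit CSV layout."""
        rows = []
        for rec in self.records:
            row: dict[str, Any] = {
                "patient_id": rec.patient_id,
                "visit_id": rec.visit_id,
                "tjc28": rec.tjc28,
                "sjc28": rec.sjc28,
                "pga": rec.pga,
                "crp_mg_l": rec.crp_mg_l,
            }
            if rec.esr_mm_h is not None:
                row["esr_mm_h"] = rec.esr_mm_h
            if rec.age is not None:
                row["age"] = rec.age
            if rec.sex is not None:
                row["sex"] = rec.sex
            if rec.rf_status is not None:
                row["rf_status"] = int(rec.rf_status)
            if rec.ccp_status is not None:
                row["ccp_status"] = int(rec.ccp_status)
            for name, flag in rec.therapy.items():
                row[f"therapy_{name}"] = int(flag)
            for name, flag in rec.comorbidities.items():
                row[f"comorbid_{name}"] = int(flag)
            for analyte, conc in rec.markers.items():
                row[analyte] = conc.value
            rows.append(row)
        return pd.DataFrame(rows)


def _parse_bool(value: Any) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("1", "true", "yes", "pos", "+"):
            return True
        if v in ("0", "false", "no", "neg", "-"):
            return False
        raise ValueError(f"unparseable boolean {value!r}")
    return bool(int(value))


def cohort_from_frame(
    df: pd.DataFrame,
    metadata: dict[str, Any] | None = None,
    marker_columns: Sequence[str] | None = None,
) -> Cohort:
    """Build a typed Cohort from a flat table, collecting row rejections.

    Columns not in the clinical set and not prefixed ``therapy_``/``comorbid_``
    are treated as marker concentrations unless ``marker_columns`` is given.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")

    if marker_columns is None:
        marker_columns = [
            c
            for c in df.columns
            if c not in _CLINICAL_COLUMNS
            and not c.startswith("therapy_")
            and not c.startswith("comorbid_")
        ]

    records: list[PatientRecord] = []
    rejections: list[RowRejection] = []
    for i, row in df.reset_index(drop=True).iterrows():
        try:
            markers = {}
            for col in marker_columns:
                raw = row[col]
                if raw is None or (isinstance(raw, float) and math.isnan(raw)):
                    continue
                units = "mg/L" if col == "CRP" else "pg/mL"
                markers[col] = MarkerConcentration(col, float(raw), units)
            therapy = {
                c[len("therapy_"):]: bool(int(row[c]))
                for c in df.columns
                if c.startswith("therapy_") and not pd.isna(row[c])
            }
            comorbid = {
                c[len("comorbid_"):]: bool(int(row[c]))
                for c in df.columns
                if c.startswith("comorbid_") and not pd.isna(row[c])
            }
            rec = PatientRecord(
                patient_id=str(row["patient_id"]),
                visit_id=str(row["visit_id"]) if "visit_id" in df.columns else "1",
                markers=markers,
                tjc28=int(row["tjc28"]),
                sjc28=int(row["sjc28"]),
                pga=float(row["pga"]),
                crp_mg_l=float(row["crp_mg_l"]),
                esr_mm_h=(
                    float(row["esr_mm_h"])
                    if "esr_mm_h" in df.columns and not pd.isna(row["esr_mm_h"])
                    else None
                ),
                age=(
                    float(row["age"])
                    if "age" in df.columns and not pd.isna(row["age"])
                    else None
                ),
                sex=(
                    str(row["sex"])
                    if "sex" in df.columns and not pd.isna(row["sex"])
                    else None
                ),
                rf_status=_parse_bool(row.get("rf_status")),
                ccp_status=_parse_bool(row.get("ccp_status")),
                therapy=therapy,
                comorbidities=comorbid,
            )
        except DomainError as exc:
            rejections.append(RowRejection(int(i), "range", str(exc)))
            continue
        except (ValueError, TypeError) as exc:
            rejections.append(RowRejection(int(i), "parse", str(exc)))
            continue
        records.append(rec)

    return Cohort(records=records, metadata=dict(metadata or {}), rejections=rejections)


def load_cohort(path: str | Path, metadata: dict[str, Any] | None = None) -> Cohort:
    """Read a cohort CSV (header row required; see column dictionary in README).

    Rows that fail type or range checks are rejected, not fatal; diagnostics
    are collected on ``Cohort.rejections``. A missing required column raises
    :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    meta = {"source": str(path)}
    meta.update(metadata or {})
    return cohort_from_frame(df, metadata=meta)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to CSV; round-trips finite decimal values."""
    cohort.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Coefficients configuration


def _build_coefficients(cfg: Mapping[str, Any]) -> AlgorithmCoefficients:
    try:
        comp_cfg = cfg["components"]
    except KeyError:
        raise ConfigError("config missing 'components' section") from None
    components = {}
    for name in COMPONENT_NAMES:
        if name not in comp_cfg:
            raise ConfigError(f"missing component model {name!r}")
        spec = comp_cfg[name]
        components[name] = ComponentModel(
            intercept=float(spec.get("intercept", 0.0)),
            coefficients={str(k): float(v) for k, v in spec.get("coefficients", {}).items()},
        )
    shrink = cfg.get("shrinkage", [[1.0, 0.0], [0.0, 1.0]])
    shrinkage = (
        (float(shrink[0][0]), float(shrink[0][1])),
        (float(shrink[1][0]), float(shrink[1][1])),
    )
    # DAS28-CRP(4)-analogous defaults; w_pga on the 0-10 PGA scale
    combination = {"w_tjc": 0.56, "w_sjc": 0.28, "w_crp": 0.36, "w_pga": 0.14, "constant": 0.96}
    combination.update({str(k): float(v) for k, v in cfg.get("combination", {}).items()})
    return AlgorithmCoefficients(
        components=components,
        shrinkage=shrinkage,
        combination=combination,
        scale=float(cfg.get("scale", 10.53)),
        offset=float(cfg.get("offset", 1.0)),
        score_min=int(cfg.get("score_min", 1)),
        score_max=int(cfg.get("score_max", 100)),
        exponent=float(cfg.get("exponent", 0.1)),
        crp_unit=str(cfg.get("crp_unit", "mg/L")),
        panel=tuple(cfg.get("panel", PANEL_ANALYTES)),
    )


def load_coefficients(path: str | Path) -> AlgorithmCoefficients:
    """Load algorithm coefficients from a YAML or JSON config file.

    Defaults are applied for scale (10.53), offset (1), score bounds (1, 100)
    and concentration exponent (0.1) when omitted. Unknown analytes or a
    missing component model raise :class:`ConfigError`.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, Mapping):
        raise ConfigError(f"config at {path} is not a mapping")
    return _build_coefficients(cfg)


def default_coefficients() -> AlgorithmCoefficients:
    """The shipped default configuration (DAS28-CRP-analogous weights)."""
    return load_coefficients(_DEFAULT_COEFFS_PATH)


def coefficients_to_dict(coeffs: AlgorithmCoefficients) -> dict[str, Any]:
    """Serialize coefficients to a plain dict (inverse of the loader)."""
    return {
        "components": {
            name: {
                "intercept": model.intercept,
                "coefficients": dict(model.coefficients),
            }
            for name, model in coeffs.components.items()
        },
        "shrinkage": [list(row) for row in coeffs.shrinkage],
        "combination": dict(coeffs.combination),
        "scale": coeffs.scale,
        "offset": coeffs.offset,
        "score_min": coeffs.score_min,
        "score_max": coeffs.score_max,
        "exponent": coeffs.exponent,
        "crp_unit": coeffs.crp_unit,
        "panel": list(coeffs.panel),
    }


def save_coefficients(coeffs: AlgorithmCoefficients, path: str | Path) -> None:
    """Write coefficients to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    data = coefficients_to_dict(coeffs)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
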