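"""Reference clinical composite disease-activity indices and category maps.

These indices (DAS28-CRP4, DAS28-ESR4, CDAI, SDAI) serve as training targets
and comparators. All coefficients are configurable but default to the
standard published values. PGA enters the DAS28 formulas on the 0-100 mm
VAS scale; convenience wrappers accept the 0-10 scale and rescale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from mbda.core import Cohort, DomainError

__all__ = [
    "DAS28_CRP_WEIGHTS",
    "das28_crp4",
    "das28_esr4",
    "cdai",
    "sdai",
    "das28_category",
    "cdai_category",
    "index_table",
    "IndexValue",
]

#: (w_tjc, w_sjc, w_crp, w_pga_mm, constant) of the four-variable DAS28-CRP.
DAS28_CRP_WEIGHTS = (0.56, 0.28, 0.36, 0.014, 0.96)

#: (w_tjc, w_sjc, w_ln_esr, w_pga_mm) of the four-variable DAS28-ESR.
DAS28_ESR_WEIGHTS = (0.56, 0.28, 0.70, 0.014)

#: DAS28-CRP category cutoffs: remission < 2.3; low <= 2.7; moderate <= 4.1.
DAS28_CRP_CUTOFFS = (2.3, 2.7, 4.1)

CATEGORIES = ("remission", "low", "moderate", "high")


@dataclass(frozen=True)
class IndexValue:
    """A computed composite index with its disease-activity category."""

    index_id: str
    value: float
    category: str | None = None


def _check_nonneg(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if v < 0:
            raise DomainError(f"{name}={v} must be non-negative")


def das28_crp4(
    tjc28: float,
    sjc28: float,
    crp_mg_l: float,
    pga_mm: float,
    weights: tuple[float, float, float, float, float] = DAS28_CRP_WEIGHTS,
) -> float:
    """Four-variable DAS28-CRP.

    ``0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.36*ln(CRP+1) + 0.014*PGA + 0.96``
    with CRP in mg/L and PGA on the 0-100 mm VAS scale.
    """
    _check_nonneg(tjc28=tjc28, sjc28=sjc28, crp_mg_l=crp_mg_l, pga_mm=pga_mm)
    w_t, w_s, w_c, w_p, const = weights
    return (
        w_t * math.sqrt(tjc28)
        + w_s * math.sqrt(sjc28)
        + w_c * math.log(crp_mg_l + 1.0)
        + w_p * pga_mm
        + const
    )


def das28_esr4(
    tjc28: float,
    sjc28: float,
    esr_mm_h: float,
    pga_mm: float,
    weights: tuple[float, float, float, float] = DAS28_ESR_WEIGHTS,
) -> float:
    """Four-variable DAS28-ESR: ``0.56*sqrt(T) + 0.28*sqrt(S) + 0.70*ln(ESR) + 0.014*PGA``."""
    _check_nonneg(tjc28=tjc28, sjc28=sjc28, pga_mm=pga_mm)
    if esr_mm_h <= 0:
        raise DomainError(f"esr_mm_h={esr_mm_h} must be positive (log term)")
    w_t, w_s, w_e, w_p = weights
    return (
        w_t * math.sqrt(tjc28)
        + w_s * math.sqrt(sjc28)
        + w_e * math.log(esr_mm_h)
        + w_p * pga_mm
    )


def cdai(tjc28: float, sjc28: float, pga_0_10: float, ega_0_10: float) -> float:
    """Clinical Disease Activity Index: TJC28 + SJC28 + PGA + evaluator global (0-10 each)."""
    _check_nonneg(tjc28=tjc28, sjc28=sjc28, pga_0_10=pga_0_10, ega_0_10=ega_0_10)
    return tjc28 + sjc28 + pga_0_10 + ega_0_10


def sdai(
    tjc28: float, sjc28: float, pga_0_10: float, ega_0_10: float, crp_mg_l: float
) -> float:
    """Simplified Disease Activity Index: CDAI + CRP in mg/dL."""
    _check_nonneg(crp_mg_l=crp_mg_l)
    return cdai(tjc28, sjc28, pga_0_10, ega_0_10) + crp_mg_l / 10.0


def das28_category(value: float, cutoffs: tuple[float, float, float] = DAS28_CRP_CUTOFFS) -> str:
    """Disease-activity category for a DAS28-CRP value.

    remission: value < 2.3; low: 2.3 <= value <= 2.7;
    moderate: 2.7 < value <= 4.1; high: value > 4.1.
    The boundary value 2.3 is assigned to "low" (the published cutoff table
    leaves it formally between the strict "<2.3" and weak "<=2.7" bounds).
    """
    rem, low, mod = cutoffs
    if value < rem:
        return "remission"
    if value <= low:
        return "low"
    if value <= mod:
        return "moderate"
    return "high"


def cdai_category(value: float) -> str:
    """Standard CDAI bands: <=2.8 remission, <=10 low, <=22 moderate, else high."""
    if value <= 2.8:
        return "remission"
    if value <= 10:
        return "low"
    if value <= 22:
        return "moderate"
    return "high"


def index_table(cohort: Cohort, ega_default: float = 0.0) -> pd.DataFrame:
    """Vectorized index computation over a cohort.

    Emits one row per (patient-visit, index); PGA recorded on the 0-10 scale
    in the cohort is multiplied by 10 for the DAS28 formulas. Indices whose
    inputs are unavailable for a record (e.g. ESR) are skipped.
    """
    rows = []
    for rec in cohort:
        pga_mm = rec.pga * 10.0
        d = das28_crp4(rec.tjc28, rec.sjc28, rec.crp_mg_l, pga_mm)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "visit_id": rec.visit_id,
                "index_id": "DAS28CRP4",
                "value": d,
                "category": das28_category(d),
            }
        )
        c = cdai(rec.tjc28, rec.sjc28, rec.pga, ega_default)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "visit_id": rec.visit_id,
                "index_id": "CDAI",
                "value": c,
                "category": cdai_category(c),
            }
        )
        s = sdai(rec.tjc28, rec.sjc28, rec.pga, ega_default, rec.crp_mg_l)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "visit_id": rec.visit_id,
                "index_id": "SDAI",
                "value": s,
                "category": None,
            }
        )
        if rec.esr_mm_h is not None and rec.esr_mm_h > 0:
            e = das28_esr4(rec.tjc28, rec.sjc28, rec.esr_mm_h, pga_mm)
            rows.append(
                {
                    "patient_id": rec.patient_id,
                    "visit_id": rec.visit_id,
                    "index_id": "DAS28ESR4",
                    "value": e,
                    "category": None,
                }
            )
    return pd.DataFrame(rows)


#: Endpoint extractors used by the prioritization stage; each maps a record
#: to a real-valued clinical measure (None when unavailable).
ENDPOINT_FUNCS: dict[str, Callable] = {
    "das28crp4": lambda r: das28_crp4(r.tjc28, r.sjc28, r.crp_mg_l, r.pga * 10.0),
    "das28esr4": lambda r: (
        das28_esr4(r.tjc28, r.sjc28, r.esr_mm_h, r.pga * 10.0)
        if r.esr_mm_h is not None and r.esr_mm_h > 0
        else None
    ),
    "cdai": lambda r: cdai(r.tjc28, r.sjc28, r.pga, 0.0),
    "sdai": lambda r: sdai(r.tjc28, r.sjc28, r.pga, 0.0, r.crp_mg_l),
    "tjc28": lambda r: float(r.tjc28),
    "sjc28": lambda r: float(r.sjc28),
    "pga": lambda r: float(r.pga),
    "crp": lambda r: float(r.crp_mg_l),
}


def endpoint_vector(cohort: Cohort, endpoint_id: str) -> np.ndarray:
    """Evaluate one named clinical endpoint over all records (NaN if missing)."""
    try:
        fn = ENDPOINT_FUNCS[endpoint_id]
    except KeyError:
        raise KeyError(
            f"unknown endpoint {endpoint_id!r}; available: {sorted(ENDPOINT_FUNCS)}"
        ) from None
    vals = [fn(rec) for rec in cohort]
    return np.array([np.nan if v is None else float(v) for v in vals])
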