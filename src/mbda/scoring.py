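"""The final scoring algorithm: component predictions, shrinkage, score.

Pipeline per record: 11 power-transformed marker concentrations feed three
linear component models (predicted TJC28, SJC28, PGA); a 2x2 shrinkage
matrix improves the two joint-count predictions by exploiting their
correlation; the improved predictions are combined with measured CRP in a
DAS28-CRP-analogous equation; the result is scaled and rounded to an
integer score in [1, 100] with four disease-activity categories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from mbda.core import (
    AlgorithmCoefficients,
    Cohort,
    DomainError,
    PatientRecord,
    ScoringInputError,
)

__all__ = [
    "MBDAResult",
    "MBDA_CUTOFFS",
    "round_half_away",
    "predict_components",
    "curds_whey_improve",
    "combine_and_scale",
    "mbda_category",
    "mbda_equivalent_of_das",
    "score_record",
    "score_cohort",
]

#: Integer score cutoffs: remission <= 25; low <= 29; moderate <= 44; high > 44.
MBDA_CUTOFFS = (25, 29, 44)


def round_half_away(x: float) -> int:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3); not banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class MBDAResult:
    """Full scoring output for one patient-visit."""

    patient_id: str
    visit_id: str
    ptjc28: float
    psjc28: float
    ppga: float
    iptjc: float
    isjc: float
    pre_scale: float
    score: int
    category: str
    crp_fraction: float
    crp_fraction_nonconstant: float


def predict_components(
    record: PatientRecord, coeffs: AlgorithmCoefficients
) -> tuple[float, float, float]:
    """Evaluate the three component models on one record.

    Each component is ``intercept + sum(w_a * conc_a**exponent)`` over that
    component's analyte set. A missing analyte raises
    :class:`~mbda.core.ScoringInputError` naming the analyte.
    """
    e = coeffs.exponent
    ptjc = coeffs.components["PTJC28"].predict(record, e)
    psjc = coeffs.components["PSJC28"].predict(record, e)
    ppga = coeffs.components["PPGA"].predict(record, e)
    return ptjc, psjc, ppga


def curds_whey_improve(
    ptjc28: float, psjc28: float, coeffs: AlgorithmCoefficients
) -> tuple[float, float]:
    """Apply the configured 2x2 shrinkage matrix to the joint-count predictions.

    Returns elementwise ``max(0, M @ (ptjc28, psjc28))``; truncation at zero
    precedes the square root taken downstream (joint counts are non-negative).
    Predicted PGA and CRP are deliberately excluded from the shrinkage.
    """
    m = coeffs.shrinkage_matrix
    improved = m @ np.array([ptjc28, psjc28], dtype=float)
    return float(max(0.0, improved[0])), float(max(0.0, improved[1]))


def combine_and_scale(
    iptjc: float,
    isjc: float,
    crp_mg_l: float,
    ppga: float,
    coeffs: AlgorithmCoefficients,
    patient_id: str = "",
    visit_id: str = "",
) -> MBDAResult:
    """Combine improved predictions with CRP and produce the integer score.

    ``pre_scale = w_tjc*sqrt(IPTJC) + w_sjc*sqrt(ISJC) + w_crp*ln(CRP+1)
    + w_pga*PPGA + constant``; then
    ``score = clamp(round(pre_scale*scale + offset), 1, 100)`` with rounding
    half away from zero. The CRP term's share of the score is reported both
    against the full score and against the non-constant portion (score minus
    the scaled combination constant).
    """
    if crp_mg_l < 0:
        raise DomainError(f"crp_mg_l={crp_mg_l} negative")
    if iptjc < 0 or isjc < 0:
        raise DomainError("improved joint-count predictions must be non-negative")
    w = coeffs.combination
    crp_term = w["w_crp"] * math.log(crp_mg_l + 1.0)
    pre_scale = (
        w["w_tjc"] * math.sqrt(iptjc)
        + w["w_sjc"] * math.sqrt(isjc)
        + crp_term
        + w["w_pga"] * ppga
        + w["constant"]
    )
    raw = pre_scale * coeffs.scale + coeffs.offset
    score = min(coeffs.score_max, max(coeffs.score_min, round_half_away(raw)))

    scaled_crp = crp_term * coeffs.scale
    crp_fraction = scaled_crp / score if score != 0 else float("nan")
    nonconstant = score - w["constant"] * coeffs.scale
    crp_fraction_nonconstant = (
        scaled_crp / nonconstant if nonconstant != 0 else float("nan")
    )
    return MBDAResult(
        patient_id=patient_id,
        visit_id=visit_id,
        ptjc28=float("nan"),
        psjc28=float("nan"),
        ppga=ppga,
        iptjc=iptjc,
        isjc=isjc,
        pre_scale=pre_scale,
        score=score,
        category=mbda_category(score, coeffs),
        crp_fraction=crp_fraction,
        crp_fraction_nonconstant=crp_fraction_nonconstant,
    )


def mbda_category(score: int, coeffs: AlgorithmCoefficients | None = None) -> str:
    """Disease-activity category of an integer score.

    <=25 remission; 26-29 low; 30-44 moderate; >=45 high. Out-of-range
    scores raise ``ValueError``.
    """
    lo = coeffs.score_min if coeffs is not None else 1
    hi = coeffs.score_max if coeffs is not None else 100
    if not lo <= score <= hi:
        raise ValueError(f"score {score} outside [{lo}, {hi}]")
    rem, low, mod = MBDA_CUTOFFS
    if score <= rem:
        return "remission"
    if score <= low:
        return "low"
    if score <= mod:
        return "moderate"
    return "high"


def mbda_equivalent_of_das(
    das_value: float, scale: float = 10.53, offset: float = 1.0
) -> int:
    """Map a DAS28-CRP value onto the integer score scale, without clamping.

    ``round(das * 10.53 + 1)`` with rounding half away from zero; used to
    derive the category cutoffs (2.3 -> 25, 2.7 -> 29, 4.1 -> 44).
    """
    if das_value < 0:
        raise DomainError(f"das_value={das_value} negative")
    return round_half_away(das_value * scale + offset)


def score_record(record: PatientRecord, coeffs: AlgorithmCoefficients) -> MBDAResult:
    """Run the full scoring pipeline on one record.

    Refuses records missing any analyte required by the configured component
    models (no imputation).
    """
    ptjc, psjc, ppga = predict_components(record, coeffs)
    iptjc, isjc = curds_whey_improve(ptjc, psjc, coeffs)
    result = combine_and_scale(
        iptjc,
        isjc,
        record.crp_mg_l,
        ppga,
        coeffs,
        patient_id=record.patient_id,
        visit_id=record.visit_id,
    )
    # dataclass is frozen; rebuild with the raw component predictions filled in
    return MBDAResult(
        patient_id=result.patient_id,
        visit_id=result.visit_id,
        ptjc28=ptjc,
        psjc28=psjc,
        ppga=ppga,
        iptjc=result.iptjc,
        isjc=result.isjc,
        pre_scale=result.pre_scale,
        score=result.score,
        category=result.category,
        crp_fraction=result.crp_fraction,
        crp_fraction_nonconstant=result.crp_fraction_nonconstant,
    )


def score_cohort(cohort: Cohort, coeffs: AlgorithmCoefficients) -> pd.DataFrame:
    """Score every record; returns one row per patient-visit.

    Raises :class:`~mbda.core.ScoringInputError` on the first record missing
    a required analyte (scoring is all-or-nothing by design).
    """
    rows = []
    for rec in cohort:
        res = score_record(rec, coeffs)
        rows.append(
            {
                "patient_id": res.patient_id,
                "visit_id": res.visit_id,
                "ptjc28": res.ptjc28,
                "psjc28": res.psjc28,
                "ppga": res.ppga,
                "iptjc": res.iptjc,
                "isjc": res.isjc,
                "pre_scale": res.pre_scale,
                "score": res.score,
                "category": res.category,
                "crp_fraction": res.crp_fraction,
                "crp_fraction_nonconstant": res.crp_fraction_nonconstant,
            }
        )
    return pd.DataFrame(rows)
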