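"""Comorbidity confounding analysis: median ratios, age/sex adjustment, FDR."""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from mbda.core import Cohort
from mbda.indices import endpoint_vector
from mbda.prioritize import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "median_ratio",
    "adjusted_association",
    "family_adjust",
    "comorbidity_report",
]


def median_ratio(values_with: Sequence[float], values_without: Sequence[float]) -> float:
    """median(with) / median(without); 1.0 means the measure is unaffected.

    Returns NaN (with a log line) when the denominator median is not
    positive, rather than raising.
    """
    w = np.asarray(values_with, dtype=float)
    wo = np.asarray(values_without, dtype=float)
    if w.size == 0 or wo.size == 0:
        raise ValueError("both groups must be nonempty")
    denom = float(np.median(wo))
    if denom <= 0:
        logger.warning("median ratio undefined: denominator median %g <= 0", denom)
        return float("nan")
    return float(np.median(w)) / denom


def adjusted_association(
    measure: Sequence[float],
    condition: Sequence[int],
    age: Sequence[float],
    sex: Sequence[int],
    log_transform: bool = False,
) -> tuple[float, float]:
    """Condition effect on a measure, adjusted for age and sex by OLS.

    Fits ``measure ~ condition + age + sex`` (sex as a single 0/1 indicator)
    and returns the condition coefficient and its p-value. Requires at least
    20 rows and both condition levels present; a collinear design raises.
    """
    y = np.asarray(measure, dtype=float)
    c = np.asarray(condition, dtype=float)
    a = np.asarray(age, dtype=float)
    s = np.asarray(sex, dtype=float)
    if not (y.size == c.size == a.size == s.size):
        raise ValueError("input length mismatch")
    if y.size < 20:
        raise ValueError(f"need n >= 20, got {y.size}")
    if len(np.unique(c)) < 2:
        raise ValueError("both condition levels must be present")
    if log_transform:
        if (y <= 0).any():
            raise ValueError("log transform requires strictly positive measures")
        y = np.log(y)
    X = sm.add_constant(np.column_stack([c, a, s]))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(y, X).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


def family_adjust(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """BH step-up across the condition x measure family.

    Returns ``(adjusted_p, significant_flags)`` with significance at
    adjusted p < q.
    """
    adj = bh_adjust(p_values)
    return adj, adj < q


def comorbidity_report(
    cohort: Cohort,
    measures: Sequence[str] = ("crp", "cdai", "das28crp4", "mbda"),
    min_prevalence: float = 0.10,
    q: float = 0.05,
    mbda_scores: Mapping[tuple[str, str], float] | None = None,
    log_transform: bool = False,
) -> pd.DataFrame:
    """Per-condition, per-measure median ratios with adjusted p-values.

    Conditions present in fewer than ``min_prevalence`` of records are
    skipped. The ``mbda`` measure requires precomputed scores keyed by
    (patient_id, visit_id). BH adjustment runs across the whole
    condition x measure family.
    """
    recs = cohort.records
    n = len(recs)
    conditions = sorted({c for r in recs for c in r.comorbidities})
    age = np.array([r.age if r.age is not None else np.nan for r in recs])
    sex = np.array([1.0 if (r.sex or "").upper().startswith("F") else 0.0 for r in recs])

    def measure_vector(measure: str) -> np.ndarray:
        if measure == "mbda":
            if mbda_scores is None:
                raise ValueError("mbda measure requested but no scores supplied")
            return np.array(
                [float(mbda_scores[(r.patient_id, r.visit_id)]) for r in recs]
            )
        return endpoint_vector(cohort, measure)

    vectors = {m: measure_vector(m) for m in measures}

    rows = []
    for cond in conditions:
        flags = np.array([bool(r.comorbidities.get(cond, False)) for r in recs])
        n_with = int(flags.sum())
        if n_with / n < min_prevalence:
            continue
        for measure in measures:
            vals = vectors[measure]
            ok = np.isfinite(vals) & np.isfinite(age)
            ratio = median_ratio(vals[flags & ok], vals[~flags & ok])
            try:
                coef, p = adjusted_association(
                    vals[ok], flags[ok].astype(int), age[ok], sex[ok],
                    log_transform=log_transform,
                )
            except ValueError as exc:
                logger.warning("adjustment failed for %s/%s: %s", cond, measure, exc)
                coef, p = float("nan"), float("nan")
            rows.append(
                dict(
                    condition=cond,
                    n_with=n_with,
                    fraction_with=n_with / n,
                    measure=measure,
                    median_ratio=ratio,
                    coefficient=coef,
                    p_value=p,
                )
            )
    report = pd.DataFrame(
        rows,
        columns=[
            "condition", "n_with", "fraction_with", "measure",
            "median_ratio", "coefficient", "p_value",
        ],
    )
    if len(report):
        valid = report["p_value"].notna()
        report["p_adjusted"] = np.nan
        report["significant"] = False
        if valid.any():
            adj, sig = family_adjust(report.loc[valid, "p_value"].to_numpy(), q=q)
            report.loc[valid, "p_adjusted"] = adj
            report.loc[valid, "significant"] = sig
    return report
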