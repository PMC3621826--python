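"""Performance evaluation: AUROC, leave-one-out CV, change correlation, CRP share."""

from __future__ import annotations

import logging
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mbda.core import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "auroc",
    "loocv_scores",
    "change_correlation",
    "crp_contribution",
    "evaluation_report",
]


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via the Mann-Whitney identity.

    The probability that a uniformly random positive outscores a uniformly
    random negative, with ties counted one half. Requires both classes.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels length mismatch")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    # midrank formulation: U / (n_pos * n_neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def loocv_scores(
    cohort: Cohort,
    trainer: Callable[[Cohort], Callable],
) -> pd.DataFrame:
    """Leave-one-patient-out cross-validated scores.

    ``trainer`` maps a training Cohort to a predictor ``record -> float``.
    The CV unit is the patient: all visits of the held-out patient leave the
    training set together, so multi-visit cohorts cannot leak within-patient
    information. A trainer failure on a fold yields NA for that patient's
    visits (logged), not a hard error.
    """
    if len(cohort) < 3:
        raise ValueError("leave-one-out needs at least 3 records")
    patient_ids = sorted({r.patient_id for r in cohort.records})
    rows = []
    for pid in patient_ids:
        train = Cohort(records=[r for r in cohort if r.patient_id != pid])
        held = [r for r in cohort if r.patient_id == pid]
        try:
            predict = trainer(train)
            preds = {(r.patient_id, r.visit_id): float(predict(r)) for r in held}
        except Exception as exc:  # noqa: BLE001 - fold failure is a data event
            logger.warning("LOOCV fold for patient %s failed: %s", pid, exc)
            preds = {(r.patient_id, r.visit_id): float("nan") for r in held}
        for r in held:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "visit_id": r.visit_id,
                    "prediction": preds[(r.patient_id, r.visit_id)],
                }
            )
    return pd.DataFrame(rows)


def change_correlation(
    deltas_a: Sequence[float], deltas_b: Sequence[float]
) -> tuple[float, float]:
    """Spearman correlation between paired within-patient changes.

    Returns ``(rho, p_value)``. Inputs must be paired and of equal length,
    with at least 3 pairs.
    """
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("unpaired rows: delta series lengths differ")
    if a.size < 3:
        raise ValueError("need at least 3 paired changes")
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)


def crp_contribution(
    results: pd.DataFrame, include_constant: bool = True
) -> tuple[float, float]:
    """Mean and SD of the per-patient CRP-term share of the score, in percent.

    With ``include_constant=True`` the share is taken against the full score;
    otherwise against the non-constant portion (score minus the scaled
    combination constant). Patients with a zero denominator are excluded
    with a warning.
    """
    col = "crp_fraction" if include_constant else "crp_fraction_nonconstant"
    if col not in results.columns:
        raise KeyError(f"results missing column {col!r}")
    frac = results[col].to_numpy(dtype=float)
    ok = np.isfinite(frac)
    if (~ok).any():
        logger.warning("%d patients excluded (zero denominator)", int((~ok).sum()))
    frac = frac[ok]
    if frac.size == 0:
        raise ValueError("no usable rows for CRP contribution")
    return float(np.mean(frac) * 100.0), float(np.std(frac, ddof=1) * 100.0 if frac.size > 1 else 0.0)


def evaluation_report(
    scores: Sequence[float],
    truth: Sequence[float],
    fixed_threshold: float = 2.67,
    median_at_or_below_is_low: bool = True,
) -> dict:
    """Correlations and AUROCs of scores against a clinical truth vector.

    Labels are "moderate/high" (positive) vs "low" per the fixed threshold
    and, separately, per the study-median threshold; values exactly at the
    median go to the low class by default.
    """
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=float)
    if s.shape != t.shape:
        raise ValueError("scores and truth length mismatch")
    pearson_r = float(stats.pearsonr(t, s)[0])
    spearman_rho = float(stats.spearmanr(t, s)[0])
    med = float(np.median(t))
    labels_fixed = (t > fixed_threshold).astype(int)
    if median_at_or_below_is_low:
        labels_median = (t > med).astype(int)
    else:
        labels_median = (t >= med).astype(int)
    report = {
        "n": int(s.size),
        "pearson_r": pearson_r,
        "spearman_rho": spearman_rho,
        "threshold_fixed": fixed_threshold,
        "threshold_median": med,
    }
    for key, labels in (("auroc_fixed", labels_fixed), ("auroc_median", labels_median)):
        try:
            report[key] = auroc(s, labels)
        except ValueError:
            report[key] = float("nan")
    return report
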