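"""Assay quality-control rules: duplicate-well CV, control ranges, imputation.

Reason codes emitted in QC reports: DUP_CV, CONTROL_RANGE, PLATE_REVIEW,
IMPUTED_LOW, IMPUTED_HIGH.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WellPair",
    "ControlReading",
    "DuplicateFlag",
    "duplicate_cv_flag",
    "control_in_range",
    "plate_review_flags",
    "impute_out_of_curve",
    "qc_report",
]


@dataclass(frozen=True)
class WellPair:
    """Duplicate-well raw signals for one sample/analyte on one plate."""

    sample_id: str
    analyte_id: str
    signal_a: float
    signal_b: float
    plate_id: str = ""

    def __post_init__(self) -> None:
        if self.signal_a < 0 or self.signal_b < 0:
            raise ValueError(
                f"negative signal for sample {self.sample_id!r}/{self.analyte_id!r}"
            )


@dataclass(frozen=True)
class ControlReading:
    """A run/process control: observed vs expected concentration with its SD."""

    control_id: str
    analyte_id: str
    observed: float
    expected: float
    sd: float
    plate_id: str = ""

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"control {self.control_id!r}: sd must be > 0")


@dataclass(frozen=True)
class DuplicateFlag:
    flagged: bool
    cv: float
    reason: str | None = None


def duplicate_cv_flag(pair: WellPair, threshold: float = 0.20) -> DuplicateFlag:
    """Flag a sample whose duplicate-well signal CV exceeds the threshold.

    CV uses the two-replicate sample (n-1) standard deviation over the mean:
    ``cv = |a - b| / (sqrt(2) * mean(a, b))``. Flagged iff cv > 0.20 by
    default. Two zero signals cannot form a CV and are flagged outright.
    """
    a, b = pair.signal_a, pair.signal_b
    mean = (a + b) / 2.0
    if mean == 0.0:
        return DuplicateFlag(flagged=True, cv=float("nan"), reason="no signal")
    cv = abs(a - b) / (math.sqrt(2.0) * mean)
    return DuplicateFlag(flagged=cv > threshold, cv=cv, reason="DUP_CV" if cv > threshold else None)


def control_in_range(reading: ControlReading, n_sd: float = 3.0) -> bool:
    """True iff the observed control lies within +/- n_sd SD of expected (inclusive)."""
    return abs(reading.observed - reading.expected) <= n_sd * reading.sd


def plate_review_flags(
    readings: Iterable[ControlReading],
    n_sd: float = 3.0,
    min_failures: int = 2,
) -> dict[tuple[str, str], int]:
    """Plates needing review: >= ``min_failures`` failed controls for one analyte.

    Returns a map (plate_id, analyte_id) -> failure count for flagged cells.
    The failure threshold defaults to 2 ("multiple" controls out of range)
    and is configurable.
    """
    failures: Counter[tuple[str, str]] = Counter()
    for r in readings:
        if not control_in_range(r, n_sd):
            failures[(r.plate_id, r.analyte_id)] += 1
    return {key: n for key, n in failures.items() if n >= min_failures}


def impute_out_of_curve(
    values: Sequence[float],
    below: Sequence[bool],
    above: Sequence[bool],
) -> list[float]:
    """Replace out-of-curve readings with the study's observed extremes.

    Below-curve readings become the minimum in-curve value observed in the
    study for that analyte; above-curve readings become the maximum. In-curve
    values pass through unchanged. All-out-of-curve input has no anchor and
    raises ``ValueError``.
    """
    values = list(values)
    below = list(below)
    above = list(above)
    if not (len(values) == len(below) == len(above)):
        raise ValueError("values/below/above must have equal length")
    if any(b and a for b, a in zip(below, above)):
        raise ValueError("a reading cannot be both below and above the curve")
    in_curve = [v for v, b, a in zip(values, below, above) if not b and not a]
    if not in_curve:
        raise ValueError("all values out of curve: no in-curve anchor")
    lo, hi = min(in_curve), max(in_curve)
    return [lo if b else hi if a else v for v, b, a in zip(values, below, above)]


def qc_report(
    pairs: Iterable[WellPair] = (),
    controls: Iterable[ControlReading] = (),
    cv_threshold: float = 0.20,
    n_sd: float = 3.0,
    min_plate_failures: int = 2,
) -> pd.DataFrame:
    """One row per QC flag with a reason code, ready to write as CSV."""
    rows = []
    controls = list(controls)
    for p in pairs:
        flag = duplicate_cv_flag(p, cv_threshold)
        if flag.flagged:
            rows.append(
                {
                    "reason": "DUP_CV",
                    "sample_id": p.sample_id,
                    "analyte_id": p.analyte_id,
                    "plate_id": p.plate_id,
                    "value": flag.cv,
                    "detail": flag.reason or "",
                }
            )
    for c in controls:
        if not control_in_range(c, n_sd):
            rows.append(
                {
                    "reason": "CONTROL_RANGE",
                    "sample_id": c.control_id,
                    "analyte_id": c.analyte_id,
                    "plate_id": c.plate_id,
                    "value": (c.observed - c.expected) / c.sd,
                    "detail": f"observed={c.observed} expected={c.expected}",
                }
            )
    for (plate, analyte), n_fail in plate_review_flags(
        controls, n_sd, min_plate_failures
    ).items():
        rows.append(
            {
                "reason": "PLATE_REVIEW",
                "sample_id": "",
                "analyte_id": analyte,
                "plate_id": plate,
                "value": float(n_fail),
                "detail": f"{n_fail} control failures",
            }
        )
    return pd.DataFrame(
        rows, columns=["reason", "sample_id", "analyte_id", "plate_id", "value", "detail"]
    )
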