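"""Synthetic RA cohort generator.

A single latent disease-activity factor drives everything: serum markers
are log-normal around an analyte baseline with a configurable loading on
the latent factor; the two joint counts are beta-binomial with a
logit-linked mean; PGA is a bounded 0-10 response; CRP is log-linked. The
DAS28-CRP of a generated record follows from its generated components, so
the cohort has the correlation structure the development pipeline assumes.
Presets approximate the marginals of the prioritization, training and
comorbidities cohorts. Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mbda.core import Cohort, MarkerConcentration, PatientRecord
from mbda.qc import WellPair

__all__ = [
    "MarkerSpec",
    "LatentComponent",
    "CohortSpec",
    "generate",
    "preset_spec",
    "PRESETS",
    "inject_out_of_curve",
    "inject_duplicates",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


@dataclass(frozen=True)
class MarkerSpec:
    """Log-normal marker model: baseline * exp(loading*z + N(0, noise_sd))."""

    baseline_median: float
    loading: float
    noise_sd: float = 0.7

    def __post_init__(self) -> None:
        if self.baseline_median <= 0:
            raise ValueError("baseline_median must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LatentComponent:
    """One mixture component of the latent disease-activity distribution."""

    weight: float
    mean: float
    sd: float


_DEFAULT_MARKERS: dict[str, MarkerSpec] = {
    "TNFRI": MarkerSpec(1200.0, 0.30, 0.5),
    "IL6": MarkerSpec(5.0, 0.90, 1.0),
    "VCAM1": MarkerSpec(500_000.0, 0.20, 0.4),
    "EGF": MarkerSpec(60.0, 0.40, 0.8),
    "VEGFA": MarkerSpec(300.0, 0.50, 0.7),
    "YKL40": MarkerSpec(80_000.0, 0.50, 0.7),
    "MMP1": MarkerSpec(4_000.0, 0.40, 0.8),
    "MMP3": MarkerSpec(20_000.0, 0.60, 0.8),
    "SAA": MarkerSpec(2_000_000.0, 0.90, 1.2),
    "LEPTIN": MarkerSpec(10_000.0, 0.15, 0.9),
    "RESISTIN": MarkerSpec(12_000.0, 0.30, 0.6),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort."""

    n: int = 200
    visits_per_patient: int = 1
    latent: tuple[LatentComponent, ...] = (LatentComponent(1.0, 0.0, 1.0),)
    markers: Mapping[str, MarkerSpec] = field(
        default_factory=lambda: dict(_DEFAULT_MARKERS)
    )
    tjc_intercept: float = _logit(5 / 28)
    tjc_slope: float = 1.0
    sjc_intercept: float = _logit(4 / 28)
    sjc_slope: float = 1.0
    joint_count_kappa: float = 30.0  # beta-binomial concentration (overdispersion)
    pga_intercept: float = -0.45
    pga_slope: float = 1.0
    pga_noise_sd: float = 0.5
    crp_log_median: float = math.log(4.0)
    crp_slope: float = 1.0
    crp_noise_sd: float = 0.7
    female_fraction: float = 0.78
    age_mean: float = 59.0
    age_sd: float = 13.0
    comorbidity_prevalence: Mapping[str, float] = field(default_factory=dict)
    comorbidity_latent_shift: Mapping[str, float] = field(default_factory=dict)
    visit_latent_sd: float = 0.3  # within-patient latent drift across visits
    name: str = "custom"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.visits_per_patient <= 0:
            raise ValueError("visits_per_patient must be positive")
        w = sum(c.weight for c in self.latent)
        if not math.isclose(w, 1.0, rel_tol=1e-6):
            raise ValueError("latent mixture weights must sum to 1")
        for name, p in self.comorbidity_prevalence.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {name!r} outside [0, 1]")
        for sd in (self.pga_noise_sd, self.crp_noise_sd, self.visit_latent_sd):
            if sd < 0:
                raise ValueError("noise sds must be >= 0")


PRESETS: dict[str, CohortSpec] = {
    # High-activity early cohort: median DAS28-CRP ~5.8 (TJC 12, SJC 16,
    # CRP 14 mg/L, PGA 5).
    "studyI-like": CohortSpec(
        n=128,
        latent=(LatentComponent(1.0, 0.0, 1.0),),
        tjc_intercept=_logit(12 / 28),
        tjc_slope=0.9,
        sjc_intercept=_logit(16 / 28),
        sjc_slope=0.8,
        pga_intercept=0.0,
        pga_slope=0.8,
        crp_log_median=math.log(14.0),
        crp_slope=0.9,
        female_fraction=0.82,
        name="studyI-like",
    ),
    # Training cohort enriched for similar numbers of low/moderate/high
    # activity patients: three-component latent mixture, wide DAS spread.
    "training-like": CohortSpec(
        n=249,
        latent=(
            LatentComponent(1 / 3, -1.3, 0.45),
            LatentComponent(1 / 3, 0.0, 0.45),
            LatentComponent(1 / 3, 1.3, 0.45),
        ),
        tjc_intercept=_logit(5 / 28),
        tjc_slope=1.2,
        sjc_intercept=_logit(4 / 28),
        sjc_slope=1.2,
        pga_intercept=_logit(0.39),
        pga_slope=1.0,
        crp_log_median=math.log(3.8),
        crp_slope=1.1,
        female_fraction=0.75,
        name="training-like",
    ),
    # Representative observational cohort with common comorbidities at their
    # observed prevalences, all with null effect on disease activity.
    "inform512-like": CohortSpec(
        n=512,
        latent=(LatentComponent(1.0, 0.0, 0.9),),
        tjc_intercept=_logit(2.5 / 28),
        tjc_slope=1.0,
        sjc_intercept=_logit(2.5 / 28),
        sjc_slope=1.0,
        pga_intercept=_logit(0.35),
        pga_slope=0.9,
        crp_log_median=math.log(4.3),
        crp_slope=1.0,
        female_fraction=0.76,
        comorbidity_prevalence={
            "hypertension": 0.44,
            "osteoarthritis": 0.34,
            "osteoporotic_fracture": 0.26,
            "degenerative_joint_disease": 0.22,
            "diabetes": 0.14,
            "asthma": 0.10,
        },
        name="inform512-like",
    ),
}


def preset_spec(name: str, **overrides) -> CohortSpec:
    """A named preset spec, optionally with field overrides."""
    try:
        spec = PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return replace(spec, **overrides) if overrides else spec


def _draw_latent(spec: CohortSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    weights = np.array([c.weight for c in spec.latent])
    comp = rng.choice(len(spec.latent), size=n, p=weights / weights.sum())
    means = np.array([c.mean for c in spec.latent])[comp]
    sds = np.array([c.sd for c in spec.latent])[comp]
    return rng.normal(means, sds)


def _beta_binomial(
    rng: np.random.Generator, n_trials: int, p_mean: np.ndarray, kappa: float
) -> np.ndarray:
    p_mean = np.clip(p_mean, 1e-6, 1 - 1e-6)
    p = rng.beta(p_mean * kappa, (1 - p_mean) * kappa)
    return rng.binomial(n_trials, p)


def generate(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Generate a cohort from a spec; bit-identical for identical seeds."""
    if seed is None:
        seed = spec.seed if spec.seed is not None else 0
    rng = np.random.default_rng(seed)
    n = spec.n

    z_patient = _draw_latent(spec, rng, n)
    female = rng.random(n) < spec.female_fraction
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, n), 18, 95)
    rf = rng.random(n) < 0.75
    ccp = rng.random(n) < 0.62

    comorbid_flags = {
        name: rng.random(n) < prev
        for name, prev in spec.comorbidity_prevalence.items()
    }
    for name, shift in spec.comorbidity_latent_shift.items():
        if name in comorbid_flags and shift != 0.0:
            z_patient = z_patient + shift * comorbid_flags[name]

    records = []
    for visit in range(spec.visits_per_patient):
        if spec.visits_per_patient == 1:
            z = z_patient
        else:
            z = z_patient + rng.normal(0.0, spec.visit_latent_sd, n)

        tjc = _beta_binomial(
            rng, 28, _sigmoid(spec.tjc_intercept + spec.tjc_slope * z),
            spec.joint_count_kappa,
        )
        sjc = _beta_binomial(
            rng, 28, _sigmoid(spec.sjc_intercept + spec.sjc_slope * z),
            spec.joint_count_kappa,
        )
        pga = 10.0 * _sigmoid(
            spec.pga_intercept + spec.pga_slope * z + rng.normal(0, spec.pga_noise_sd, n)
        )
        crp = np.exp(
            spec.crp_log_median + spec.crp_slope * z + rng.normal(0, spec.crp_noise_sd, n)
        )
        marker_values = {
            analyte: ms.baseline_median
            * np.exp(ms.loading * z + rng.normal(0, ms.noise_sd, n))
            for analyte, ms in spec.markers.items()
        }
        for i in range(n):
            markers = {
                analyte: MarkerConcentration(analyte, float(vals[i]))
                for analyte, vals in marker_values.items()
            }
            records.append(
                PatientRecord(
                    patient_id=f"P{i + 1:04d}",
                    visit_id=str(visit + 1),
                    markers=markers,
                    tjc28=int(tjc[i]),
                    sjc28=int(sjc[i]),
                    pga=float(np.clip(pga[i], 0, 10)),
                    crp_mg_l=float(crp[i]),
                    age=float(age[i]),
                    sex="F" if female[i] else "M",
                    rf_status=bool(rf[i]),
                    ccp_status=bool(ccp[i]),
                    comorbidities={k: bool(v[i]) for k, v in comorbid_flags.items()},
                )
            )
    return Cohort(records=records, metadata={"spec": spec.name, "seed": seed, "n": n})


def inject_out_of_curve(
    cohort: Cohort,
    below_rate: float = 0.0,
    above_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Flag a random subset of marker readings as below/above the curve.

    Returns a long table (patient_id, visit_id, analyte_id, value, below,
    above) suitable for :func:`mbda.qc.impute_out_of_curve` per analyte.
    """
    for name, rate in (("below_rate", below_rate), ("above_rate", above_rate)):
        if not 0 <= rate <= 1:
            raise ValueError(f"{name}={rate} outside [0, 1]")
    if below_rate + above_rate > 1:
        raise ValueError("below_rate + above_rate must not exceed 1")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in cohort:
        for analyte, conc in rec.markers.items():
            u = rng.random()
            rows.append(
                dict(
                    patient_id=rec.patient_id,
                    visit_id=rec.visit_id,
                    analyte_id=analyte,
                    value=conc.value,
                    below=u < below_rate,
                    above=below_rate <= u < below_rate + above_rate,
                )
            )
    return pd.DataFrame(rows)


def inject_duplicates(
    cohort: Cohort, cv: float = 0.05, seed: int = 0
) -> list[WellPair]:
    """Duplicate-well signal pairs around each marker reading.

    Each well signal is the concentration perturbed by multiplicative
    Gaussian noise with coefficient of variation ``cv`` (cv=0 gives
    identical pairs); signals are truncated at zero.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    pairs = []
    for rec in cohort:
        for analyte, conc in rec.markers.items():
            a, b = conc.value * (1.0 + cv * rng.standard_normal(2))
            pairs.append(
                WellPair(
                    sample_id=f"{rec.patient_id}:{rec.visit_id}",
                    analyte_id=analyte,
                    signal_a=float(max(0.0, a)),
                    signal_b=float(max(0.0, b)),
                    plate_id="plate1",
                )
            )
    return pairs
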