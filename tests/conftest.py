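from __future__ import annotations

import numpy as np
import pytest

from mbda.core import Cohort, MarkerConcentration, PatientRecord, default_coefficients
from mbda.synth import generate, preset_spec


@pytest.fixture(scope="session")
def coeffs():
    return default_coefficients()


def make_record(
    patient_id: str = "P1",
    visit_id: str = "1",
    marker_values: dict[str, float] | None = None,
    **kwargs,
) -> PatientRecord:
    markers = {
        a: MarkerConcentration(a, v) for a, v in (marker_values or {}).items()
    }
    return PatientRecord(patient_id=patient_id, visit_id=visit_id, markers=markers, **kwargs)


@pytest.fixture
def full_panel_record(coeffs):
    """A record carrying every analyte any configured component model needs."""
    needed = set()
    for model in coeffs.components.values():
        needed |= set(model.coefficients)
    values = {a: 1000.0 for a in needed}
    return make_record(
        marker_values=values, tjc28=6, sjc28=4, pga=3.0, crp_mg_l=10.0
    )


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    return generate(preset_spec("training-like", n=80), seed=11)


@pytest.fixture(scope="session")
def training_cohort() -> Cohort:
    return generate(preset_spec("training-like", n=250), seed=5)
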