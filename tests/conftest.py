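"""Shared factories for building small EHR fixtures programmatically."""

from datetime import datetime
from typing import Optional

import pytest

from abxlot.records import (
    AdmissionRecord,
    Focus,
    IndicationKind,
    IndicationLabel,
    PrescriptionRecord,
    Route,
    Setting,
)


def make_label(
    kind: str = "empirical",
    focus: Optional[str] = "sepsis e.c.i.",
    spec: Optional[str] = None,
    free_text: Optional[str] = None,
) -> IndicationLabel:
    k = IndicationKind(kind)
    return IndicationLabel(
        kind=k,
        focus=Focus(focus) if (focus and k is not IndicationKind.open_text) else None,
        specification=spec,
        free_text=free_text,
    )


def make_rx(
    rid: str = "R1",
    pid: str = "P1",
    drug: str = "ceftriaxone",
    atc: str = "J01DD04",
    start: str = "2020-06-01T10:00",
    stop: Optional[str] = "2020-06-05T10:00",
    label: Optional[IndicationLabel] = None,
    dose: float = 2000.0,
    route: str = "intravenous",
    setting: str = "inpatient",
) -> PrescriptionRecord:
    return PrescriptionRecord(
        prescription_id=rid,
        patient_id=pid,
        drug_name=drug,
        atc_code=atc,
        dose_mg_per_day=dose,
        route=Route(route),
        start_ts=datetime.fromisoformat(start),
        stop_ts=datetime.fromisoformat(stop) if stop else None,
        indication=label,
        setting=Setting(setting),
    )


def make_adm(
    aid: str = "A1",
    pid: str = "P1",
    admit: str = "2020-06-01T08:00",
    discharge: str = "2020-06-10T12:00",
    via_er: bool = False,
    icu: bool = False,
    age: float = 50.0,
) -> AdmissionRecord:
    return AdmissionRecord(
        admission_id=aid,
        patient_id=pid,
        admit_ts=datetime.fromisoformat(admit),
        discharge_ts=datetime.fromisoformat(discharge),
        via_er=via_er,
        icu_stay=icu,
        age_years=age,
    )


@pytest.fixture
def therapy_label() -> IndicationLabel:
    return make_label("targeted", "UTI", "complicated")
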