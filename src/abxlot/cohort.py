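"""Cohort classification: admission linkage, acquisition, LOT and exclusions.

Courses are linked to the admission during which they started; infections
are community-acquired (CA) when therapy started less than 48 h after
admission and hospital-acquired (HA) when it started later.  Length of
treatment (LOT) is the inclusive calendar-day span of the course,
irrespective of how many agents or doses are given on each day, and the
post-discharge part is the number of course days strictly after the
discharge date.  Finally an ordered exclusion cascade with strict count
conservation selects the analysable cohort.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from datetime import timedelta
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, model_validator

from .config import Thresholds
from .records import (
    AdmissionRecord,
    DataIntegrityError,
    ExclusionReason,
    TreatmentCourse,
)

log = logging.getLogger(__name__)

__all__ = [
    "ExclusionFlow",
    "EXCLUSION_ORDER",
    "attach_admission",
    "classify_acquisition",
    "compute_lot",
    "compute_post_discharge",
    "classify_courses",
    "attribute_exclusions",
    "apply_exclusions",
]

#: Fixed application order of the cascade; a course is attributed to its
#: first matching reason (criteria may overlap).
EXCLUSION_ORDER: tuple[ExclusionReason, ...] = (
    ExclusionReason.not_hospital_initiated,
    ExclusionReason.admission_under_12h,
    ExclusionReason.pediatric,
    ExclusionReason.icu_during_admission,
    ExclusionReason.multiple_final_diagnoses,
    ExclusionReason.open_text_indication,
    ExclusionReason.duration_over_45d,
    ExclusionReason.readmitted_during_course,
)


class ExclusionFlow(BaseModel):
    """Flow-diagram arithmetic of the exclusion cascade."""

    steps: list[tuple[ExclusionReason, int]]
    n_input: int
    n_remaining: int

    @model_validator(mode="after")
    def _conserved(self) -> "ExclusionFlow":
        if self.n_input != self.n_remaining + sum(n for _, n in self.steps):
            raise ValueError("exclusion flow does not conserve course counts")
        return self

    def to_frame(self) -> pd.DataFrame:
        rows = [{"step": "input", "n": self.n_input}]
        rows += [{"step": f"excluded:{r.value}", "n": n} for r, n in self.steps]
        rows.append({"step": "remaining", "n": self.n_remaining})
        return pd.DataFrame(rows)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _admissions_by_patient(
    admissions: Iterable[AdmissionRecord],
) -> dict[str, list[AdmissionRecord]]:
    by_patient: dict[str, list[AdmissionRecord]] = defaultdict(list)
    for adm in admissions:
        by_patient[adm.patient_id].append(adm)
    for patient_id, adms in by_patient.items():
        adms.sort(key=lambda a: (a.admit_ts, a.admission_id))
        for prev, nxt in zip(adms, adms[1:]):
            if nxt.admit_ts < prev.discharge_ts:
                raise DataIntegrityError(
                    f"overlapping admissions for patient {patient_id}: "
                    f"{prev.admission_id} and {nxt.admission_id}"
                )
    return by_patient


def attach_admission(
    course: TreatmentCourse, admissions: Iterable[AdmissionRecord]
) -> TreatmentCourse:
    """Link a course to the admission it was initiated in.

    The admission whose [admit, discharge] window contains the course start
    is linked (ER-initiated courses link to the admission the ER visit
    opened).  A course that starts *before* any admission but runs into one
    — therapy begun in the community and continued in hospital — is linked
    to that admission and flagged ``pre_admission``.  Courses with no
    qualifying admission are flagged ``not_hospital_initiated``.
    """
    by_patient = _admissions_by_patient(admissions)
    adms = by_patient.get(course.patient_id, [])
    flags = set(course.exclusion_flags)

    containing = [a for a in adms if a.admit_ts <= course.start_ts <= a.discharge_ts]
    if containing:
        return course.model_copy(update={"admission_id": containing[0].admission_id})

    spanned = [a for a in adms if course.start_ts < a.admit_ts <= course.stop_ts]
    if spanned:
        flags.add("pre_admission")
        return course.model_copy(
            update={"admission_id": spanned[0].admission_id, "exclusion_flags": flags}
        )

    flags.add("not_hospital_initiated")
    return course.model_copy(update={"exclusion_flags": flags})


def classify_acquisition(
    course: TreatmentCourse,
    admission: AdmissionRecord,
    thresholds: Thresholds | None = None,
) -> str:
    """CA when therapy started less than 48 h after admission, else HA.

    Exactly 48 h classifies as HA (conservative nosocomial attribution).
    Courses that started before the admission (pre-admission therapy
    continued in hospital) are CA by construction.
    """
    thresholds = thresholds or Thresholds()
    if course.start_ts < admission.admit_ts:
        return "CA"
    delta = course.start_ts - admission.admit_ts
    return "CA" if delta < timedelta(hours=thresholds.ca_ha_boundary_hours) else "HA"


def compute_lot(course: TreatmentCourse) -> int:
    """LOT in calendar days: inclusive span from start date to stop date."""
    return (course.stop_ts.date() - course.start_ts.date()).days + 1


def compute_post_discharge(
    course: TreatmentCourse, admission: AdmissionRecord
) -> tuple[int, float]:
    """Course calendar days strictly after the discharge date, and their
    percentage of the LOT."""
    lot = compute_lot(course)
    days = (course.stop_ts.date() - admission.discharge_ts.date()).days
    days = max(0, min(days, lot))
    pct = 100.0 * days / lot
    return days, pct


def classify_courses(
    courses: Iterable[TreatmentCourse],
    admissions: Iterable[AdmissionRecord],
    thresholds: Thresholds | None = None,
) -> list[TreatmentCourse]:
    """Attach admissions and fill acquisition, LOT and post-discharge fields."""
    thresholds = thresholds or Thresholds()
    admissions = list(admissions)
    adm_by_id = {a.admission_id: a for a in admissions}
    out = []
    for course in courses:
        course = attach_admission(course, admissions)
        update: dict = {"lot_days": compute_lot(course)}
        if course.admission_id is not None:
            adm = adm_by_id[course.admission_id]
            update["acquisition"] = classify_acquisition(course, adm, thresholds)
            days, pct = compute_post_discharge(course, adm)
            update["post_discharge_days"] = days
            update["pct_of_lot_post_discharge"] = pct
        out.append(course.model_copy(update=update))
    return out


def _matches(
    course: TreatmentCourse,
    reason: ExclusionReason,
    adm_by_id: dict[str, AdmissionRecord],
    by_patient: dict[str, list[AdmissionRecord]],
    thresholds: Thresholds,
) -> bool:
    adm = adm_by_id.get(course.admission_id) if course.admission_id else None
    if reason is ExclusionReason.not_hospital_initiated:
        return "not_hospital_initiated" in course.exclusion_flags or adm is None
    if adm is None:
        # remaining criteria are admission-dependent except the course-level ones
        if reason is ExclusionReason.multiple_final_diagnoses:
            return "multiple_final_diagnoses" in course.exclusion_flags
        if reason is ExclusionReason.open_text_indication:
            return "open_text_indication" in course.exclusion_flags
        if reason is ExclusionReason.duration_over_45d:
            return (course.lot_days or 0) > thresholds.max_course_days
        return False
    if reason is ExclusionReason.admission_under_12h:
        return adm.duration_hours < thresholds.min_admission_hours
    if reason is ExclusionReason.pediatric:
        return adm.age_years < thresholds.pediatric_age_years
    if reason is ExclusionReason.icu_during_admission:
        return adm.icu_stay
    if reason is ExclusionReason.multiple_final_diagnoses:
        return "multiple_final_diagnoses" in course.exclusion_flags
    if reason is ExclusionReason.open_text_indication:
        return "open_text_indication" in course.exclusion_flags
    if reason is ExclusionReason.duration_over_45d:
        return (course.lot_days or 0) > thresholds.max_course_days
    if reason is ExclusionReason.readmitted_during_course:
        for other in by_patient.get(course.patient_id, []):
            if other.admission_id == course.admission_id:
                continue
            if other.duration_hours < thresholds.min_admission_hours:
                continue  # the readmission itself must count as a hospitalization
            if course.start_ts < other.admit_ts < course.stop_ts:
                return True
        return False
    raise AssertionError(f"unhandled reason {reason}")


def attribute_exclusions(
    courses: Iterable[TreatmentCourse],
    admissions: Iterable[AdmissionRecord],
    thresholds: Thresholds | None = None,
    order: tuple[ExclusionReason, ...] = EXCLUSION_ORDER,
) -> list[TreatmentCourse]:
    """Return all courses with ``exclusion_reason`` set to the first matching
    reason of the cascade (None when the course is included)."""
    thresholds = thresholds or Thresholds()
    admissions = list(admissions)
    adm_by_id = {a.admission_id: a for a in admissions}
    by_patient = _admissions_by_patient(admissions)

    processed: list[TreatmentCourse] = []
    for course in courses:
        attributed: Optional[ExclusionReason] = None
        for reason in order:
            if _matches(course, reason, adm_by_id, by_patient, thresholds):
                attributed = reason
                break
        processed.append(course.model_copy(update={"exclusion_reason": attributed}))
    return processed


def apply_exclusions(
    courses: Iterable[TreatmentCourse],
    admissions: Iterable[AdmissionRecord],
    thresholds: Thresholds | None = None,
    order: tuple[ExclusionReason, ...] = EXCLUSION_ORDER,
) -> tuple[list[TreatmentCourse], ExclusionFlow]:
    """Apply the exclusion cascade; each course counts once, at its first
    matching reason.  Returns the included courses and a conserved
    :class:`ExclusionFlow`."""
    processed = attribute_exclusions(courses, admissions, thresholds, order)
    counts = {reason: 0 for reason in order}
    included: list[TreatmentCourse] = []
    for course in processed:
        if course.exclusion_reason is None:
            included.append(course)
        else:
            counts[course.exclusion_reason] += 1

    flow = ExclusionFlow(
        steps=[(reason, counts[reason]) for reason in order],
        n_input=len(processed),
        n_remaining=len(included),
    )
    log.info(
        "exclusion cascade: %d input -> %d remaining (%s)",
        flow.n_input,
        flow.n_remaining,
        ", ".join(f"{r.value}={n}" for r, n in flow.steps if n),
    )
    return included, flow
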