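"""Treatment-course construction from raw prescription records.

The builder implements the core data flow of the surveillance method:

1. *Therapeutic filtering* — keep only ATC J01 antibacterials, drop
   prescriptions registered as prophylaxis, and drop unlabeled prescriptions
   that match the presumed-prophylaxis drug/duration/dose rules.
2. *Course assembly* — per patient, sort prescriptions by start time and
   greedily link each one to the open course when it starts within the
   linkage gap (24 h, inclusive) of the course's latest effective stop;
   otherwise a new course opens.  Overlapping prescriptions always share a
   course.  Outpatient prescriptions participate identically, which is what
   captures post-discharge therapy.
3. *Indication resolution* — the earliest registered indication marks the
   start of the course; the last registered indication is the definitive
   one (the course's final diagnosis).

A prescription that lacks a stop date contributes its own start as its
effective stop; when such a prescription determines the course stop, the
course is truncated to the start *date* of that (last) prescription and
flagged ``truncated_missing_stop``.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from datetime import datetime, timedelta
from typing import Iterable, Optional

from .config import COTRIMOXAZOLE_NAMES, ProphylaxisRuleSet, normalize_drug
from .records import (
    IndicationKind,
    PrescriptionRecord,
    TreatmentCourse,
)

log = logging.getLogger(__name__)

__all__ = [
    "effective_stop",
    "prescription_duration_days",
    "is_presumed_prophylaxis",
    "filter_therapeutic",
    "partition_therapeutic",
    "assemble_courses",
    "resolve_indications",
]


def effective_stop(rx: PrescriptionRecord) -> datetime:
    """Stop timestamp used for linkage: the recorded stop, or — for
    prescriptions without one — the prescription's own start."""
    return rx.stop_ts if rx.stop_ts is not None else rx.start_ts


def prescription_duration_days(rx: PrescriptionRecord) -> Optional[int]:
    """Inclusive calendar-day span of a prescription; None without a stop date."""
    if rx.stop_ts is None:
        return None
    return (rx.stop_ts.date() - rx.start_ts.date()).days + 1


def is_presumed_prophylaxis(
    rx: PrescriptionRecord, rules: ProphylaxisRuleSet | None = None
) -> bool:
    """Classify an unlabeled prescription as presumed prophylaxis.

    True iff the drug is one of the long-term prophylactic agents prescribed
    for more than 28 days, or co-trimoxazole at low daily dose (<= 480 mg)
    for more than 14 days / at higher dose for more than 50 days.  Duration
    is the inclusive calendar-day span; prescriptions without a stop date are
    never presumed prophylactic here.
    """
    rules = rules or ProphylaxisRuleSet()
    duration = prescription_duration_days(rx)
    if duration is None:
        return False
    drug = normalize_drug(rx.drug_name)
    if drug in rules.normalized_drugs():
        return duration > rules.long_term_threshold_days
    if drug in COTRIMOXAZOLE_NAMES:
        if rx.dose_mg_per_day <= rules.cotrimoxazole_low_dose_mg:
            return duration > rules.cotrimoxazole_low_dose_threshold_days
        return duration > rules.cotrimoxazole_high_dose_threshold_days
    return False


def partition_therapeutic(
    prescriptions: Iterable[PrescriptionRecord],
    rules: ProphylaxisRuleSet | None = None,
) -> dict[str, list[PrescriptionRecord]]:
    """Split prescriptions into kept therapeutic records and the three
    removal buckets (non-J01, labeled prophylaxis, presumed prophylaxis)."""
    rules = rules or ProphylaxisRuleSet()
    out: dict[str, list[PrescriptionRecord]] = {
        "kept": [],
        "non_j01": [],
        "labeled_prophylaxis": [],
        "presumed_prophylaxis": [],
    }
    for rx in prescriptions:
        if not rx.is_antibacterial:
            out["non_j01"].append(rx)
        elif rx.indication is not None and rx.indication.kind is IndicationKind.prophylaxis:
            out["labeled_prophylaxis"].append(rx)
        elif rx.indication is None and is_presumed_prophylaxis(rx, rules):
            out["presumed_prophylaxis"].append(rx)
        else:
            out["kept"].append(rx)
    return out


def filter_therapeutic(
    prescriptions: Iterable[PrescriptionRecord],
    rules: ProphylaxisRuleSet | None = None,
) -> list[PrescriptionRecord]:
    """Retain therapeutic J01 prescriptions; removal counts are logged."""
    parts = partition_therapeutic(prescriptions, rules)
    log.info(
        "therapeutic filter: kept %d | removed %d non-J01, %d labeled prophylaxis, "
        "%d presumed prophylaxis",
        len(parts["kept"]),
        len(parts["non_j01"]),
        len(parts["labeled_prophylaxis"]),
        len(parts["presumed_prophylaxis"]),
    )
    return parts["kept"]


def _sorted_members(prescriptions: Iterable[PrescriptionRecord]) -> list[PrescriptionRecord]:
    # stable deterministic order: simultaneous starts break ties on id
    return sorted(prescriptions, key=lambda rx: (rx.start_ts, rx.prescription_id))


def assemble_courses(
    prescriptions: Iterable[PrescriptionRecord],
    gap_hours: float = 24.0,
) -> list[TreatmentCourse]:
    """Greedily link per-patient prescriptions into treatment courses.

    A prescription joins the open course when its start is no later than the
    course's latest effective stop plus ``gap_hours`` (inclusive comparison:
    a gap of exactly 24 h still links).  Every input prescription ends up in
    exactly one course.
    """
    gap = timedelta(hours=gap_hours)
    by_patient: dict[str, list[PrescriptionRecord]] = defaultdict(list)
    for rx in prescriptions:
        by_patient[rx.patient_id].append(rx)

    courses: list[TreatmentCourse] = []
    for patient_id in sorted(by_patient):
        members = _sorted_members(by_patient[patient_id])
        open_group: list[PrescriptionRecord] = []
        groups: list[list[PrescriptionRecord]] = []
        frontier: Optional[datetime] = None
        for rx in members:
            if open_group and frontier is not None and rx.start_ts <= frontier + gap:
                open_group.append(rx)
                frontier = max(frontier, effective_stop(rx))
            else:
                if open_group:
                    groups.append(open_group)
                open_group = [rx]
                frontier = effective_stop(rx)
        if open_group:
            groups.append(open_group)

        for ordinal, group in enumerate(groups, start=1):
            courses.append(_make_course(patient_id, ordinal, group))
    return courses


def _make_course(
    patient_id: str, ordinal: int, group: list[PrescriptionRecord]
) -> TreatmentCourse:
    start_ts = group[0].start_ts
    # the member whose effective stop is latest determines the course stop
    stop_rx = max(group, key=lambda rx: (effective_stop(rx), rx.prescription_id))
    truncated = stop_rx.stop_ts is None
    stop_ts = effective_stop(stop_rx)
    if truncated:
        # course stops on the start *date* of the last open-ended prescription
        stop_ts = datetime.combine(stop_rx.start_ts.date(), datetime.min.time())
        stop_ts = max(stop_ts, start_ts)
    return TreatmentCourse(
        course_id=f"{patient_id}-{ordinal:03d}",
        patient_id=patient_id,
        member_prescriptions=group,
        start_ts=start_ts,
        stop_ts=stop_ts,
        truncated_missing_stop=truncated,
    )


def _label_identity(label) -> tuple:
    if label.kind is IndicationKind.open_text:
        return ("open_text", label.free_text or "")
    return ("therapy", label.focus.value if label.focus else "", label.specification or "")


def resolve_indications(course: TreatmentCourse) -> TreatmentCourse:
    """Attach first and definitive indications and annotation flags.

    The first registered indication (earliest-starting labeled member) marks
    the start of the course; the last registered indication is the definitive
    one.  Courses whose latest-starting labeled members carry more than one
    distinct therapy indication are flagged ``multiple_final_diagnoses``;
    open-text or absent indications flag ``open_text_indication``.
    """
    members = _sorted_members(course.member_prescriptions)
    labeled = [rx for rx in members if rx.indication is not None]
    flags = set(course.exclusion_flags)

    if not labeled:
        flags.update({"unlabeled", "open_text_indication"})
        return course.model_copy(update={"exclusion_flags": flags})

    first = labeled[0].indication
    last_start = max(rx.start_ts for rx in labeled)
    finalists = [rx for rx in labeled if rx.start_ts == last_start]
    definitive = finalists[0].indication  # deterministic: sorted by (start, id)

    therapy_identities = {
        _label_identity(rx.indication)
        for rx in finalists
        if rx.indication.kind is not IndicationKind.open_text
    }
    if len(therapy_identities) > 1:
        flags.add("multiple_final_diagnoses")
    if any(rx.indication.kind is IndicationKind.open_text for rx in labeled):
        flags.add("open_text_indication")

    return course.model_copy(
        update={
            "first_indication": first,
            "definitive_indication": definitive,
            "exclusion_flags": flags,
        }
    )
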