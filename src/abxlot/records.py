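"""Domain record types and CSV interchange for antibiotic-course surveillance.

The surveillance pipeline consumes three tabular extracts from a hospital
EHR — antibiotic prescriptions (with their registered indications),
admissions, and optionally manual-review verdicts — and emits treatment
courses, exclusion-flow tallies and summary tables.  This module defines
the record types, their invariants, and loss-less CSV readers/writers for
all of them.

Conventions
-----------
* Timestamps are timezone-naive ISO 8601 at minute resolution
  (``2020-06-01T13:30``); calendar dates are obtained by truncation.
* CSV files are UTF-8, comma-separated, with a mandatory header row.
  Unknown extra columns are ignored with a warning; missing required
  columns are a parse error.
* Readers never silently drop rows: a malformed row either raises a
  :class:`ParseError` naming the row, or (with ``errors="collect"``) is
  returned in the rejected list so that ``parsed + rejected == input``.
"""

from __future__ import annotations

import enum
import logging
from datetime import datetime
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

log = logging.getLogger(__name__)

__all__ = [
    "Route",
    "Setting",
    "IndicationKind",
    "Focus",
    "UTI_SPECIFICATIONS",
    "RTI_SPECIFICATIONS",
    "IndicationLabel",
    "PrescriptionRecord",
    "AdmissionRecord",
    "ExclusionReason",
    "TreatmentCourse",
    "ValidationStratum",
    "ErrorCause",
    "ValidationRecord",
    "ParseError",
    "DataIntegrityError",
    "ReadResult",
    "read_prescriptions",
    "write_prescriptions",
    "read_admissions",
    "write_admissions",
    "read_validation",
    "write_validation",
    "write_courses",
    "read_courses",
]


class ParseError(ValueError):
    """A CSV row or file violates the input contract; message names the row."""


class DataIntegrityError(ValueError):
    """Cross-record inconsistency, e.g. overlapping admissions for one patient."""


class Route(str, enum.Enum):
    oral = "oral"
    intravenous = "intravenous"
    other = "other"


class Setting(str, enum.Enum):
    inpatient = "inpatient"
    outpatient = "outpatient"
    er = "er"


class IndicationKind(str, enum.Enum):
    empirical = "empirical"
    targeted = "targeted"
    prophylaxis = "prophylaxis"
    open_text = "open_text"


class Focus(str, enum.Enum):
    """Tract-level infection focus, as offered by the indication registration tool."""

    intra_abdominal = "intra-abdominal"
    uti = "UTI"
    rti = "RTI"
    bone_joint = "bone/joint"
    cns = "CNS"
    ent = "ENT"
    febrile_neutropenia = "febrile neutropenia"
    gastro_enteritis = "gastro-enteritis"
    gynaecological = "gynaecological"
    cvl = "CVL"
    mediastinitis = "mediastinitis"
    sab = "SAB"
    sepsis_eci = "sepsis e.c.i."
    skin_soft_tissue = "skin/soft tissue"
    other = "other"


#: Sub-type vocabulary for urinary-tract infections.
UTI_SPECIFICATIONS = frozenset(
    {"cystitis", "complicated", "kidney transplant", "catheter-related", "other"}
)
#: Sub-type vocabulary for respiratory-tract infections.
RTI_SPECIFICATIONS = frozenset(
    {"CAP-m", "CAP-s", "HAP", "COPD", "aspiration", "abscess/empyema", "other"}
)


class IndicationLabel(BaseModel):
    """Registered indication of a prescription.

    ``kind`` records whether the prescriber selected empirical therapy,
    targeted therapy, prophylaxis, or typed free text instead.  Therapy
    indications carry a tract-level ``focus``; urinary- and respiratory-tract
    infections carry a further ``specification``.
    """

    model_config = ConfigDict(frozen=True)

    kind: IndicationKind
    focus: Optional[Focus] = None
    specification: Optional[str] = None
    free_text: Optional[str] = None

    @model_validator(mode="after")
    def _check_structure(self) -> "IndicationLabel":
        if self.kind is IndicationKind.open_text:
            if self.focus is not None:
                raise ValueError("open_text indication must not carry a focus")
        else:
            if self.free_text is not None:
                raise ValueError("free_text is only allowed for open_text indications")
            if self.kind in (IndicationKind.empirical, IndicationKind.targeted) and self.focus is None:
                raise ValueError(f"{self.kind.value} indication requires a focus")
        if self.specification is not None:
            if self.focus is Focus.uti:
                if self.specification not in UTI_SPECIFICATIONS:
                    raise ValueError(f"unknown UTI specification {self.specification!r}")
            elif self.focus is Focus.rti:
                if self.specification not in RTI_SPECIFICATIONS:
                    raise ValueError(f"unknown RTI specification {self.specification!r}")
            else:
                raise ValueError("specification is only allowed for UTI or RTI focus")
        return self

    def key(self) -> str:
        """Stable display key, e.g. ``"UTI-cystitis"`` or ``"intra-abdominal"``."""
        if self.kind is IndicationKind.open_text:
            return "open_text"
        if self.focus is None:
            return self.kind.value
        if self.specification:
            return f"{self.focus.value}-{self.specification}"
        return self.focus.value

    def site_key(self) -> str:
        """Tract-level key with UTI/RTI sub-types collapsed."""
        if self.kind is IndicationKind.open_text:
            return "open_text"
        return self.focus.value if self.focus else self.kind.value


class PrescriptionRecord(BaseModel):
    """One drug order: the atomic input unit of the pipeline."""

    model_config = ConfigDict(frozen=True)

    prescription_id: str
    patient_id: str
    drug_name: str
    atc_code: str
    dose_mg_per_day: float = 0.0
    route: Route = Route.other
    start_ts: datetime
    stop_ts: Optional[datetime] = None
    indication: Optional[IndicationLabel] = None
    setting: Setting = Setting.inpatient

    @field_validator("atc_code")
    @classmethod
    def _nonempty_atc(cls, v: str) -> str:
        if not v:
            raise ValueError("atc_code must be non-empty")
        return v

    @field_validator("dose_mg_per_day")
    @classmethod
    def _nonneg_dose(cls, v: float) -> float:
        if v < 0:
            raise ValueError("dose_mg_per_day must be non-negative")
        return v

    @model_validator(mode="after")
    def _check_times(self) -> "PrescriptionRecord":
        if self.stop_ts is not None and self.stop_ts < self.start_ts:
            raise ValueError("stop_ts must be >= start_ts")
        return self

    @property
    def is_antibacterial(self) -> bool:
        """True when the ATC code falls under J01 (systemic antibacterials)."""
        return self.atc_code.startswith("J01")


class AdmissionRecord(BaseModel):
    """One hospitalization window, with the attributes used for inclusion."""

    model_config = ConfigDict(frozen=True)

    admission_id: str
    patient_id: str
    admit_ts: datetime
    discharge_ts: datetime
    via_er: bool = False
    icu_stay: bool = False
    age_years: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "AdmissionRecord":
        if self.discharge_ts <= self.admit_ts:
            raise ValueError("discharge_ts must be after admit_ts")
        if self.age_years < 0:
            raise ValueError("age_years must be non-negative")
        return self

    @property
    def duration_hours(self) -> float:
        return (self.discharge_ts - self.admit_ts).total_seconds() / 3600.0


class ExclusionReason(str, enum.Enum):
    """Reasons of the exclusion cascade, in application order."""

    not_hospital_initiated = "not_hospital_initiated"
    admission_under_12h = "admission_under_12h"
    pediatric = "pediatric"
    icu_during_admission = "icu_during_admission"
    multiple_final_diagnoses = "multiple_final_diagnoses"
    open_text_indication = "open_text_indication"
    duration_over_45d = "duration_over_45d"
    readmitted_during_course = "readmitted_during_course"


class TreatmentCourse(BaseModel):
    """An assembled per-patient treatment episode.

    A course is a maximal run of therapeutic prescriptions for one patient in
    which each prescription starts no more than the linkage gap (24 h by
    default) after the latest prior stop.  Fields beyond the members are
    filled progressively by the pipeline: indications by the resolver,
    admission linkage / acquisition / LOT / post-discharge by the cohort
    classifier, and the attributed exclusion reason by the cascade.
    """

    course_id: str
    patient_id: str
    member_prescriptions: list[PrescriptionRecord]
    start_ts: datetime
    stop_ts: datetime
    first_indication: Optional[IndicationLabel] = None
    definitive_indication: Optional[IndicationLabel] = None
    lot_days: Optional[int] = None
    acquisition: str = "unclassified"  # CA | HA | unclassified
    admission_id: Optional[str] = None
    post_discharge_days: int = 0
    pct_of_lot_post_discharge: float = 0.0
    exclusion_flags: set[str] = set()
    exclusion_reason: Optional[ExclusionReason] = None
    truncated_missing_stop: bool = False

    @model_validator(mode="after")
    def _check(self) -> "TreatmentCourse":
        for rx in self.member_prescriptions:
            if rx.patient_id != self.patient_id:
                raise ValueError("member prescriptions must share the course patient_id")
        if self.lot_days is not None:
            if self.lot_days < 1:
                raise ValueError("lot_days must be a positive integer")
            if self.post_discharge_days > self.lot_days:
                raise ValueError("post_discharge_days cannot exceed lot_days")
        if self.post_discharge_days < 0:
            raise ValueError("post_discharge_days must be non-negative")
        return self

    @property
    def drug_names(self) -> list[str]:
        """Member drug names, de-duplicated, in order of first appearance."""
        seen: list[str] = []
        for rx in self.member_prescriptions:
            if rx.drug_name not in seen:
                seen.append(rx.drug_name)
        return seen


class ValidationStratum(str, enum.Enum):
    uti = "UTI"
    rti = "RTI"
    iai = "IAI"
    other = "other"
    extended = "extended"


class ErrorCause(str, enum.Enum):
    transfer = "transfer"
    pre_admission_start = "pre_admission_start"
    mislabeled_prophylaxis = "mislabeled_prophylaxis"
    opat = "opat"
    single_dose_dosing = "single_dose_dosing"
    other = "other"


class ValidationRecord(BaseModel):
    """Reviewer verdicts for one sampled course.

    ``indication_correct_site`` optionally records whether the indication is
    correct at tract level (UTI/RTI sub-type mistakes forgiven); when absent
    it defaults to ``indication_correct``.
    """

    model_config = ConfigDict(frozen=True)

    course_id: str
    stratum: ValidationStratum
    indication_correct: bool
    lot_matches_prescriptions: bool
    lot_matches_notes: bool
    indication_correct_site: Optional[bool] = None
    error_cause: Optional[ErrorCause] = None

    @model_validator(mode="after")
    def _check(self) -> "ValidationRecord":
        if self.error_cause is not None and self.lot_matches_notes:
            raise ValueError("error_cause is only allowed when lot_matches_notes is false")
        return self

    @property
    def site_correct(self) -> bool:
        return (
            self.indication_correct
            if self.indication_correct_site is None
            else self.indication_correct_site
        )


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

PRESCRIPTION_COLUMNS = [
    "prescription_id",
    "patient_id",
    "drug_name",
    "atc_code",
    "dose_mg_per_day",
    "route",
    "start_ts",
    "stop_ts",
    "indication_kind",
    "indication_focus",
    "indication_specification",
    "indication_free_text",
    "setting",
]

ADMISSION_COLUMNS = [
    "admission_id",
    "patient_id",
    "admit_ts",
    "discharge_ts",
    "via_er",
    "icu_stay",
    "age_years",
]

VALIDATION_COLUMNS = [
    "course_id",
    "stratum",
    "indication_correct",
    "lot_matches_prescriptions",
    "lot_matches_notes",
    "indication_correct_site",
    "error_cause",
]

COURSE_COLUMNS = [
    "course_id",
    "patient_id",
    "final_diagnosis",
    "start_ts",
    "stop_ts",
    "lot_days",
    "drug_names",
    "acquisition",
    "post_discharge_days",
    "pct_of_lot_post_discharge",
    "exclusion_flags",
    "exclusion_reason",
    "truncated_missing_stop",
    "admission_id",
    "first_indication_kind",
    "first_indication_focus",
    "first_indication_specification",
    "first_indication_free_text",
    "definitive_indication_kind",
    "definitive_indication_focus",
    "definitive_indication_specification",
    "definitive_indication_free_text",
    "member_prescription_ids",
]


class ReadResult(BaseModel):
    """Outcome of a collecting read: parsed records plus rejected rows."""

    model_config = ConfigDict(arbitrary_types_allowed=True)

    records: list
    rejected: list[tuple[int, str]]  # (1-based data row number, reason)

    @property
    def n_input(self) -> int:
        return len(self.records) + len(self.rejected)


def _fmt_ts(ts: Optional[datetime]) -> str:
    return "" if ts is None else ts.isoformat(timespec="minutes")


def _parse_ts(raw: str, row: int, column: str) -> datetime:
    try:
        return datetime.fromisoformat(raw)
    except ValueError as exc:
        raise ParseError(f"row {row}: malformed timestamp in {column!r}: {raw!r}") from exc


def _parse_opt_ts(raw: str, row: int, column: str) -> Optional[datetime]:
    return None if raw == "" else _parse_ts(raw, row, column)


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f", ""}


def _parse_bool(raw: str, row: int, column: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ParseError(f"row {row}: malformed boolean in {column!r}: {raw!r}")


def _load_frame(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        log.warning("%s: ignoring unknown column(s): %s", path, ", ".join(extra))
    return df


def _parse_indication(row: dict, rownum: int) -> Optional[IndicationLabel]:
    kind_raw = row.get("indication_kind", "").strip()
    if kind_raw == "":
        return None
    focus_raw = row.get("indication_focus", "").strip()
    spec_raw = row.get("indication_specification", "").strip()
    text_raw = row.get("indication_free_text", "").strip()
    try:
        kind = IndicationKind(kind_raw)
    except ValueError:
        log.warning(
            "row %d: unknown indication kind %r mapped to open_text", rownum, kind_raw
        )
        return IndicationLabel(kind=IndicationKind.open_text, free_text=kind_raw)
    if kind is IndicationKind.open_text:
        return IndicationLabel(kind=kind, free_text=text_raw or None)
    focus: Optional[Focus] = None
    if focus_raw:
        try:
            focus = Focus(focus_raw)
        except ValueError:
            log.warning(
                "row %d: unknown indication focus %r mapped to open_text", rownum, focus_raw
            )
            return IndicationLabel(kind=IndicationKind.open_text, free_text=focus_raw)
    try:
        return IndicationLabel(kind=kind, focus=focus, specification=spec_raw or None)
    except ValueError as exc:
        log.warning("row %d: invalid indication (%s); mapped to open_text", rownum, exc)
        return IndicationLabel(
            kind=IndicationKind.open_text,
            free_text=f"{focus_raw} {spec_raw}".strip() or None,
        )


def _prescription_from_row(row: dict, rownum: int) -> PrescriptionRecord:
    try:
        route = Route(row["route"]) if row["route"] else Route.other
    except ValueError:
        raise ParseError(f"row {rownum}: unknown route {row['route']!r}")
    try:
        setting = Setting(row["setting"]) if row["setting"] else Setting.inpatient
    except ValueError:
        raise ParseError(f"row {rownum}: unknown setting {row['setting']!r}")
    try:
        dose = float(row["dose_mg_per_day"]) if row["dose_mg_per_day"] else 0.0
    except ValueError:
        raise ParseError(
            f"row {rownum}: malformed dose_mg_per_day {row['dose_mg_per_day']!r}"
        )
    try:
        return PrescriptionRecord(
            prescription_id=row["prescription_id"],
            patient_id=row["patient_id"],
            drug_name=row["drug_name"],
            atc_code=row["atc_code"],
            dose_mg_per_day=dose,
            route=route,
            start_ts=_parse_ts(row["start_ts"], rownum, "start_ts"),
            stop_ts=_parse_opt_ts(row["stop_ts"], rownum, "stop_ts"),
            indication=_parse_indication(row, rownum),
            setting=setting,
        )
    except ParseError:
        raise
    except ValueError as exc:
        raise ParseError(f"row {rownum}: {exc}")


def read_prescriptions(path, errors: str = "raise"):
    """Read a prescriptions CSV.

    With ``errors="raise"`` (default) the first malformed row aborts with a
    :class:`ParseError` naming the row.  With ``errors="collect"`` a
    :class:`ReadResult` is returned whose ``records + rejected`` account for
    every input row.
    """
    df = _load_frame(path, PRESCRIPTION_COLUMNS)
    records: list[PrescriptionRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            records.append(_prescription_from_row(row, i))
        except ParseError as exc:
            if errors == "raise":
                raise
            rejected.append((i, str(exc)))
    log.info("read %d prescriptions from %s (%d rejected)", len(records), path, len(rejected))
    if errors == "collect":
        return ReadResult(records=records, rejected=rejected)
    return records


def write_prescriptions(records: Iterable[PrescriptionRecord], path) -> None:
    rows = []
    for rx in records:
        ind = rx.indication
        rows.append(
            {
                "prescription_id": rx.prescription_id,
                "patient_id": rx.patient_id,
                "drug_name": rx.drug_name,
                "atc_code": rx.atc_code,
                "dose_mg_per_day": repr(rx.dose_mg_per_day),
                "route": rx.route.value,
                "start_ts": _fmt_ts(rx.start_ts),
                "stop_ts": _fmt_ts(rx.stop_ts),
                "indication_kind": ind.kind.value if ind else "",
                "indication_focus": ind.focus.value if ind and ind.focus else "",
                "indication_specification": (ind.specification or "") if ind else "",
                "indication_free_text": (ind.free_text or "") if ind else "",
                "setting": rx.setting.value,
            }
        )
    pd.DataFrame(rows, columns=PRESCRIPTION_COLUMNS).to_csv(path, index=False)


def read_admissions(path, errors: str = "raise"):
    """Read an admissions CSV; same error contract as :func:`read_prescriptions`."""
    df = _load_frame(path, ADMISSION_COLUMNS)
    records: list[AdmissionRecord] = []
    rejected: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            try:
                age = float(row["age_years"]) if row["age_years"] else 0.0
            except ValueError:
                raise ParseError(f"row {i}: malformed age_years {row['age_years']!r}")
            try:
                records.append(
                    AdmissionRecord(
                        admission_id=row["admission_id"],
                        patient_id=row["patient_id"],
                        admit_ts=_parse_ts(row["admit_ts"], i, "admit_ts"),
                        discharge_ts=_parse_ts(row["discharge_ts"], i, "discharge_ts"),
                        via_er=_parse_bool(row["via_er"], i, "via_er"),
                        icu_stay=_parse_bool(row["icu_stay"], i, "icu_stay"),
                        age_years=age,
                    )
                )
            except ParseError:
                raise
            except ValueError as exc:
                raise ParseError(f"row {i}: {exc}")
        except ParseError as exc:
            if errors == "raise":
                raise
            rejected.append((i, str(exc)))
    log.info("read %d admissions from %s (%d rejected)", len(records), path, len(rejected))
    if errors == "collect":
        return ReadResult(records=records, rejected=rejected)
    return records


def write_admissions(records: Iterable[AdmissionRecord], path) -> None:
    rows = [
        {
            "admission_id": a.admission_id,
            "patient_id": a.patient_id,
            "admit_ts": _fmt_ts(a.admit_ts),
            "discharge_ts": _fmt_ts(a.discharge_ts),
            "via_er": str(a.via_er).lower(),
            "icu_stay": str(a.icu_stay).lower(),
            "age_years": repr(a.age_years),
        }
        for a in records
    ]
    pd.DataFrame(rows, columns=ADMISSION_COLUMNS).to_csv(path, index=False)


def read_validation(path) -> list[ValidationRecord]:
    df = _load_frame(path, VALIDATION_COLUMNS)
    records = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            stratum = ValidationStratum(row["stratum"])
        except ValueError:
            raise ParseError(f"row {i}: unknown stratum {row['stratum']!r}")
        cause_raw = row["error_cause"].strip()
        try:
            cause = ErrorCause(cause_raw) if cause_raw else None
        except ValueError:
            raise ParseError(f"row {i}: unknown error_cause {cause_raw!r}")
        site_raw = row["indication_correct_site"].strip()
        try:
            records.append(
                ValidationRecord(
                    course_id=row["course_id"],
                    stratum=stratum,
                    indication_correct=_parse_bool(
                        row["indication_correct"], i, "indication_correct"
                    ),
                    lot_matches_prescriptions=_parse_bool(
                        row["lot_matches_prescriptions"], i, "lot_matches_prescriptions"
                    ),
                    lot_matches_notes=_parse_bool(
                        row["lot_matches_notes"], i, "lot_matches_notes"
                    ),
                    indication_correct_site=(
                        None if site_raw == "" else _parse_bool(site_raw, i, "indication_correct_site")
                    ),
                    error_cause=cause,
                )
            )
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}")
    log.info("read %d validation records from %s", len(records), path)
    return records


def write_validation(records: Iterable[ValidationRecord], path) -> None:
    rows = [
        {
            "course_id": r.course_id,
            "stratum": r.stratum.value,
            "indication_correct": str(r.indication_correct).lower(),
            "lot_matches_prescriptions": str(r.lot_matches_prescriptions).lower(),
            "lot_matches_notes": str(r.lot_matches_notes).lower(),
            "indication_correct_site": (
                "" if r.indication_correct_site is None else str(r.indication_correct_site).lower()
            ),
            "error_cause": r.error_cause.value if r.error_cause else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=VALIDATION_COLUMNS).to_csv(path, index=False)


def _ind_cols(prefix: str, ind: Optional[IndicationLabel]) -> dict:
    return {
        f"{prefix}_kind": ind.kind.value if ind else "",
        f"{prefix}_focus": ind.focus.value if ind and ind.focus else "",
        f"{prefix}_specification": (ind.specification or "") if ind else "",
        f"{prefix}_free_text": (ind.free_text or "") if ind else "",
    }


def write_courses(courses: Iterable[TreatmentCourse], path) -> None:
    """Write one row per course: final diagnosis, start/stop, total duration,
    drug names (joined with ";") plus acquisition, post-discharge days and
    exclusion bookkeeping.  Column order is fixed."""
    rows = []
    for c in courses:
        row = {
            "course_id": c.course_id,
            "patient_id": c.patient_id,
            "final_diagnosis": c.definitive_indication.key() if c.definitive_indication else "",
            "start_ts": _fmt_ts(c.start_ts),
            "stop_ts": _fmt_ts(c.stop_ts),
            "lot_days": "" if c.lot_days is None else str(c.lot_days),
            "drug_names": ";".join(c.drug_names),
            "acquisition": c.acquisition,
            "post_discharge_days": str(c.post_discharge_days),
            "pct_of_lot_post_discharge": repr(c.pct_of_lot_post_discharge),
            "exclusion_flags": ";".join(sorted(c.exclusion_flags)),
            "exclusion_reason": c.exclusion_reason.value if c.exclusion_reason else "",
            "truncated_missing_stop": str(c.truncated_missing_stop).lower(),
            "admission_id": c.admission_id or "",
            "member_prescription_ids": ";".join(
                rx.prescription_id for rx in c.member_prescriptions
            ),
        }
        row.update(_ind_cols("first_indication", c.first_indication))
        row.update(_ind_cols("definitive_indication", c.definitive_indication))
        rows.append(row)
    pd.DataFrame(rows, columns=COURSE_COLUMNS).to_csv(path, index=False)


def _label_from_cols(row: dict, prefix: str) -> Optional[IndicationLabel]:
    kind = row[f"{prefix}_kind"].strip()
    if kind == "":
        return None
    focus = row[f"{prefix}_focus"].strip()
    return IndicationLabel(
        kind=IndicationKind(kind),
        focus=Focus(focus) if focus else None,
        specification=row[f"{prefix}_specification"].strip() or None,
        free_text=row[f"{prefix}_free_text"].strip() or None,
    )


def read_courses(path, prescriptions: Optional[Iterable[PrescriptionRecord]] = None) -> list[TreatmentCourse]:
    """Read a courses CSV.  When the originating prescriptions are supplied,
    member records are rebuilt from the stored prescription ids; otherwise the
    member list is left empty (summary-level use)."""
    by_id = {}
    if prescriptions is not None:
        by_id = {rx.prescription_id: rx for rx in prescriptions}
    df = _load_frame(path, COURSE_COLUMNS)
    courses = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        member_ids = [m for m in row["member_prescription_ids"].split(";") if m]
        members = []
        if by_id:
            try:
                members = [by_id[m] for m in member_ids]
            except KeyError as exc:
                raise ParseError(f"row {i}: unknown member prescription id {exc}")
        try:
            courses.append(
                TreatmentCourse(
                    course_id=row["course_id"],
                    patient_id=row["patient_id"],
                    member_prescriptions=members,
                    start_ts=_parse_ts(row["start_ts"], i, "start_ts"),
                    stop_ts=_parse_ts(row["stop_ts"], i, "stop_ts"),
                    first_indication=_label_from_cols(row, "first_indication"),
                    definitive_indication=_label_from_cols(row, "definitive_indication"),
                    lot_days=int(row["lot_days"]) if row["lot_days"] else None,
                    acquisition=row["acquisition"] or "unclassified",
                    admission_id=row["admission_id"] or None,
                    post_discharge_days=int(row["post_discharge_days"] or 0),
                    pct_of_lot_post_discharge=float(row["pct_of_lot_post_discharge"] or 0.0),
                    exclusion_flags=set(f for f in row["exclusion_flags"].split(";") if f),
                    exclusion_reason=(
                        ExclusionReason(row["exclusion_reason"]) if row["exclusion_reason"] else None
                    ),
                    truncated_missing_stop=_parse_bool(
                        row["truncated_missing_stop"], i, "truncated_missing_stop"
                    ),
                )
            )
        except ParseError:
            raise
        except ValueError as exc:
            raise ParseError(f"row {i}: {exc}")
    return courses
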