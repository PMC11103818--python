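"""Surveillance outputs: summary tables, validation sampling, error rates.

The summary mirrors the standard stewardship presentation: per indication
and acquisition class (CA/HA), the number of courses, median LOT with
interquartile range, and post-discharge therapy fractions.  The validation
workflow draws a stratified random sample of courses for manual chart
review (5% of UTI, RTI and intra-abdominal infections, 5% of the rest and
20% of courses longer than 45 days) and turns reviewer verdicts into
error-rate tables, overall and split by CA/HA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .records import (
    Focus,
    IndicationKind,
    IndicationLabel,
    TreatmentCourse,
    ValidationRecord,
    ValidationStratum,
)

log = logging.getLogger(__name__)

__all__ = [
    "round_half_up",
    "SurveillanceSummary",
    "summarize",
    "SamplingPlan",
    "assign_stratum",
    "draw_validation_sample",
    "ErrorRateReport",
    "compute_error_rates",
    "realize_tallies",
    "tabulate_error_causes",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero, matching how the tables are presented."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pct(numerator: int, denominator: int) -> float:
    return round_half_up(100.0 * numerator / denominator) if denominator else 0.0


# ---------------------------------------------------------------------------
# Summary (per indication x acquisition)
# ---------------------------------------------------------------------------


@dataclass
class SurveillanceSummary:
    """Per-(indication, acquisition) LOT distribution plus post-discharge metrics.

    ``table`` rows: indication, acquisition, n, pct_of_acquisition,
    lot_median, lot_q1, lot_q3.  ``post_discharge`` rows per acquisition:
    pct_with_post_discharge and mean_pct_of_lot_post_discharge (among
    courses with any post-discharge part).
    """

    table: pd.DataFrame
    post_discharge: pd.DataFrame
    totals: dict[str, int] = field(default_factory=dict)

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _quantiles(values: Sequence[int]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    q1, med, q3 = np.quantile(arr, [0.25, 0.5, 0.75])  # linear interpolation
    return float(med), float(q1), float(q3)


def summarize(courses: Iterable[TreatmentCourse]) -> SurveillanceSummary:
    """Build the per-indication / per-acquisition summary for included courses."""
    courses = list(courses)
    acq_totals: dict[str, int] = {}
    for c in courses:
        acq_totals[c.acquisition] = acq_totals.get(c.acquisition, 0) + 1

    groups: dict[tuple[str, str], list[TreatmentCourse]] = {}
    for c in courses:
        key = c.definitive_indication.key() if c.definitive_indication else "unlabeled"
        groups.setdefault((key, c.acquisition), []).append(c)

    rows = []
    for (indication, acquisition) in sorted(groups):
        members = groups[(indication, acquisition)]
        lots = [c.lot_days for c in members if c.lot_days is not None]
        med, q1, q3 = _quantiles(lots) if lots else (float("nan"),) * 3
        rows.append(
            {
                "indication": indication,
                "acquisition": acquisition,
                "n": len(members),
                "pct_of_acquisition": _pct(len(members), acq_totals[acquisition]),
                "lot_median": med,
                "lot_q1": q1,
                "lot_q3": q3,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "indication",
            "acquisition",
            "n",
            "pct_of_acquisition",
            "lot_median",
            "lot_q1",
            "lot_q3",
        ],
    )

    pd_rows = []
    for acquisition in sorted(acq_totals):
        members = [c for c in courses if c.acquisition == acquisition]
        with_pd = [c for c in members if c.post_discharge_days > 0]
        mean_pct = (
            float(np.mean([c.pct_of_lot_post_discharge for c in with_pd])) if with_pd else 0.0
        )
        pd_rows.append(
            {
                "acquisition": acquisition,
                "n": len(members),
                "pct_with_post_discharge": _pct(len(with_pd), len(members)),
                "mean_pct_of_lot_post_discharge": round_half_up(mean_pct),
            }
        )
    post_discharge = pd.DataFrame(
        pd_rows,
        columns=["acquisition", "n", "pct_with_post_discharge", "mean_pct_of_lot_post_discharge"],
    )
    return SurveillanceSummary(table=table, post_discharge=post_discharge, totals=acq_totals)


# ---------------------------------------------------------------------------
# Stratified validation sampling
# ---------------------------------------------------------------------------


class SamplingPlan(BaseModel):
    """Stratified validation sampling fractions.

    Courses longer than ``extended_lot_days`` form the "extended" stratum
    (sampled at 20%, with precedence); the remainder stratify by definitive
    indication into UTI, RTI, IAI and other, each sampled at 5%.
    """

    model_config = ConfigDict(frozen=True)

    fractions: dict[ValidationStratum, float] = {
        ValidationStratum.uti: 0.05,
        ValidationStratum.rti: 0.05,
        ValidationStratum.iai: 0.05,
        ValidationStratum.other: 0.05,
        ValidationStratum.extended: 0.20,
    }
    extended_lot_days: int = 45
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SamplingPlan":
        for stratum, f in self.fractions.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"fraction for {stratum.value} must be in (0, 1]")
        return self

    def sample_size(self, stratum: ValidationStratum, stratum_size: int) -> int:
        if stratum_size == 0:
            return 0
        n = int(np.floor(self.fractions[stratum] * stratum_size + 0.5))
        return max(1, min(n, stratum_size))


def assign_stratum(course: TreatmentCourse, plan: SamplingPlan | None = None) -> ValidationStratum:
    """Extended-duration courses take precedence; otherwise stratify by the
    definitive indication's tract."""
    plan = plan or SamplingPlan()
    if (course.lot_days or 0) > plan.extended_lot_days:
        return ValidationStratum.extended
    ind = course.definitive_indication
    if ind is not None and ind.kind is not IndicationKind.open_text:
        if ind.focus is Focus.uti:
            return ValidationStratum.uti
        if ind.focus is Focus.rti:
            return ValidationStratum.rti
        if ind.focus is Focus.intra_abdominal:
            return ValidationStratum.iai
    return ValidationStratum.other


def draw_validation_sample(
    courses: Iterable[TreatmentCourse], plan: SamplingPlan | None = None
) -> list[str]:
    """Seeded stratified simple random sample (without replacement) of course ids."""
    plan = plan or SamplingPlan()
    strata: dict[ValidationStratum, list[str]] = {s: [] for s in plan.fractions}
    for c in courses:
        strata[assign_stratum(c, plan)].append(c.course_id)

    rng = np.random.default_rng(plan.seed)
    sampled: list[str] = []
    for stratum in plan.fractions:
        ids = sorted(strata[stratum])
        n = plan.sample_size(stratum, len(ids))
        if n == 0:
            log.info("validation sampling: stratum %s is empty", stratum.value)
            continue
        take = rng.choice(len(ids), size=n, replace=False)
        sampled.extend(ids[i] for i in sorted(take))
        log.info("validation sampling: %s -> %d of %d", stratum.value, n, len(ids))
    return sampled


# ---------------------------------------------------------------------------
# Error-rate reporting
# ---------------------------------------------------------------------------

_STRATUM_ROW_ORDER = [
    ValidationStratum.iai,
    ValidationStratum.rti,
    ValidationStratum.uti,
    ValidationStratum.other,
    ValidationStratum.extended,
]


@dataclass
class ErrorRateReport:
    """Error-rate table: one row per validation category plus total and CA/HA.

    Each row carries the validated denominator and, for each of the three
    checks (registered indication vs notes, calculated LOT vs prescriptions,
    calculated LOT vs notes), the incorrect count and its percentage of the
    denominator, rounded half-up to one decimal.  ``site_level_error_pct`` is
    the pooled indication error rate with UTI/RTI sub-type mistakes forgiven.
    """

    table: pd.DataFrame
    site_level_error_pct: float

    def row(self, category: str) -> pd.Series:
        return self.table.set_index("category").loc[category]

    def write_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _rate_row(category: str, records: Sequence[ValidationRecord]) -> dict:
    n = len(records)
    ind_err = sum(1 for r in records if not r.indication_correct)
    rx_err = sum(1 for r in records if not r.lot_matches_prescriptions)
    notes_err = sum(1 for r in records if not r.lot_matches_notes)
    return {
        "category": category,
        "n_validated": n,
        "n_indication_incorrect": ind_err,
        "indication_error_pct": _pct(ind_err, n),
        "n_lot_rx_incorrect": rx_err,
        "lot_rx_error_pct": _pct(rx_err, n),
        "n_lot_notes_incorrect": notes_err,
        "lot_notes_error_pct": _pct(notes_err, n),
    }


def compute_error_rates(
    records: Iterable[ValidationRecord], courses: Iterable[TreatmentCourse]
) -> ErrorRateReport:
    """Tally reviewer verdicts into per-category and CA/HA error rates.

    Every record must join a course (by ``course_id``) so that the CA/HA
    rows can be formed; a record with an unknown course id is an error.
    """
    records = list(records)
    course_by_id = {c.course_id: c for c in courses}
    for r in records:
        if r.course_id not in course_by_id:
            raise KeyError(f"validation record references unknown course {r.course_id!r}")

    rows = []
    for stratum in _STRATUM_ROW_ORDER:
        subset = [r for r in records if r.stratum is stratum]
        if subset:
            rows.append(_rate_row(stratum.value, subset))
    rows.append(_rate_row("total", records))
    for acq, label in (("CA", "CAI"), ("HA", "HAI")):
        subset = [r for r in records if course_by_id[r.course_id].acquisition == acq]
        if subset:
            rows.append(_rate_row(label, subset))

    site_err = sum(1 for r in records if not r.site_correct)
    return ErrorRateReport(
        table=pd.DataFrame(rows),
        site_level_error_pct=_pct(site_err, len(records)),
    )


def realize_tallies(
    tallies: dict[ValidationStratum, dict],
) -> tuple[list[ValidationRecord], list[TreatmentCourse]]:
    """Construct a record-level dataset realizing published-style error tallies.

    ``tallies`` maps a stratum to a dict with integer counts::

        n_ca, n_ha                      stratum sizes per acquisition
        ind_err_ca, ind_err_ha          incorrect registered indication
        rx_err_ca, rx_err_ha            LOT wrong vs prescriptions
        notes_err_ca, notes_err_ha      LOT wrong vs clinical notes
        site_forgiven_ca, site_forgiven_ha   indication errors that are
                                             sub-type-only (correct at tract level)

    Returns validation records plus matching placeholder courses so that
    :func:`compute_error_rates` reproduces exactly those tallies.  Used for
    worked-example arithmetic; the error flags are assigned to the first
    records of each block, which does not affect any rate.
    """
    from datetime import datetime, timedelta

    stratum_focus = {
        ValidationStratum.iai: (Focus.intra_abdominal, None),
        ValidationStratum.rti: (Focus.rti, "CAP-m"),
        ValidationStratum.uti: (Focus.uti, "cystitis"),
        ValidationStratum.other: (Focus.sepsis_eci, None),
        ValidationStratum.extended: (Focus.bone_joint, None),
    }
    records: list[ValidationRecord] = []
    courses: list[TreatmentCourse] = []
    t0 = datetime(2021, 1, 1, 12, 0)
    serial = 0
    for stratum, t in tallies.items():
        focus, spec = stratum_focus[stratum]
        label = IndicationLabel(kind=IndicationKind.targeted, focus=focus, specification=spec)
        for acq in ("ca", "ha"):
            n = t.get(f"n_{acq}", 0)
            ind_err = t.get(f"ind_err_{acq}", 0)
            rx_err = t.get(f"rx_err_{acq}", 0)
            notes_err = t.get(f"notes_err_{acq}", 0)
            forgiven = t.get(f"site_forgiven_{acq}", 0)
            for i in range(n):
                serial += 1
                cid = f"V{serial:05d}"
                courses.append(
                    TreatmentCourse(
                        course_id=cid,
                        patient_id=f"PV{serial:05d}",
                        member_prescriptions=[],
                        start_ts=t0,
                        stop_ts=t0 + timedelta(days=4),
                        definitive_indication=label,
                        lot_days=5,
                        acquisition=acq.upper(),
                    )
                )
                incorrect = i < ind_err
                records.append(
                    ValidationRecord(
                        course_id=cid,
                        stratum=stratum,
                        indication_correct=not incorrect,
                        indication_correct_site=(True if incorrect and i < forgiven else None),
                        lot_matches_prescriptions=not (i < rx_err),
                        lot_matches_notes=not (i < notes_err),
                    )
                )
    return records, courses


def tabulate_error_causes(records: Iterable[ValidationRecord]) -> pd.DataFrame:
    """Tally causes among courses whose LOT disagreed with the clinical notes.

    Returns a frame (cause, n, pct) where pct is the share of the
    notes-mismatched subset; records without a recorded cause fall into
    "other".  Empty when nothing mismatched.
    """
    mismatched = [r for r in records if not r.lot_matches_notes]
    if not mismatched:
        return pd.DataFrame(columns=["cause", "n", "pct"])
    counts: dict[str, int] = {}
    for r in mismatched:
        cause = r.error_cause.value if r.error_cause else "other"
        counts[cause] = counts.get(cause, 0) + 1
    rows = [
        {"cause": cause, "n": n, "pct": _pct(n, len(mismatched))}
        for cause, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["cause", "n", "pct"])
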