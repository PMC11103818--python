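"""Admission linkage, CA/HA classification, LOT and the exclusion cascade."""

import itertools
from datetime import datetime

import pytest

from abxlot.cohort import (
    EXCLUSION_ORDER,
    ExclusionFlow,
    apply_exclusions,
    attach_admission,
    classify_acquisition,
    classify_courses,
    compute_lot,
    compute_post_discharge,
)
from abxlot.courses import assemble_courses, resolve_indications
from abxlot.records import DataIntegrityError, ExclusionReason

from .conftest import make_adm, make_label, make_rx


def course_between(start, stop, pid="P1", label=None, rid="R1"):
    (course,) = assemble_courses(
        [make_rx(rid=rid, pid=pid, start=start, stop=stop, label=label)]
    )
    return resolve_indications(course)


class TestAttachAdmission:
    def test_course_during_admission_links(self):
        course = course_between("2020-06-01T14:00", "2020-06-04T10:00")
        adm = make_adm(admit="2020-06-01T08:00", discharge="2020-06-06T10:00")
        assert attach_admission(course, [adm]).admission_id == "A1"

    def test_course_after_discharge_unlinked(self):
        course = course_between("2020-06-12T10:00", "2020-06-14T10:00")
        adm = make_adm(admit="2020-06-01T08:00", discharge="2020-06-10T10:00")
        linked = attach_admission(course, [adm])
        assert linked.admission_id is None
        assert "not_hospital_initiated" in linked.exclusion_flags

    def test_er_initiated_course_links_to_opened_admission(self):
        # ER arrival at 08:00 becomes the admission; therapy starts minutes later
        course = course_between("2020-06-01T08:30", "2020-06-03T10:00")
        adm = make_adm(admit="2020-06-01T08:00", discharge="2020-06-05T10:00", via_er=True)
        assert attach_admission(course, [adm]).admission_id == "A1"

    def test_pre_admission_course_links_with_flag(self):
        # therapy begun in the community, continued during admission
        course = course_between("2020-06-01T10:00", "2020-06-08T10:00")
        adm = make_adm(admit="2020-06-03T08:00", discharge="2020-06-09T10:00")
        linked = attach_admission(course, [adm])
        assert linked.admission_id == "A1"
        assert "pre_admission" in linked.exclusion_flags

    def test_overlapping_admissions_are_a_data_error(self):
        course = course_between("2020-06-01T10:00", "2020-06-04T10:00")
        adms = [
            make_adm(aid="A1", admit="2020-06-01T08:00", discharge="2020-06-05T10:00"),
            make_adm(aid="A2", admit="2020-06-04T08:00", discharge="2020-06-07T10:00"),
        ]
        with pytest.raises(DataIntegrityError, match="overlapping"):
            attach_admission(course, adms)


class TestAcquisition:
    def test_start_20h_after_admission_is_ca(self):
        course = course_between("2020-06-02T04:00", "2020-06-05T10:00")
        adm = make_adm(admit="2020-06-01T08:00")
        assert classify_acquisition(course, adm) == "CA"

    def test_start_60h_after_admission_is_ha(self):
        course = course_between("2020-06-03T20:00", "2020-06-05T10:00")
        adm = make_adm(admit="2020-06-01T08:00")
        assert classify_acquisition(course, adm) == "HA"

    def test_exactly_48h_is_ha(self):
        course = course_between("2020-06-03T08:00", "2020-06-05T10:00")
        adm = make_adm(admit="2020-06-01T08:00")
        assert classify_acquisition(course, adm) == "HA"

    def test_pre_admission_start_is_ca(self):
        course = course_between("2020-05-30T08:00", "2020-06-05T10:00")
        adm = make_adm(admit="2020-06-01T08:00")
        assert classify_acquisition(course, adm) == "CA"


class TestLot:
    def test_lot_counts_calendar_days_inclusive(self):
        course = course_between("2020-06-01T22:00", "2020-06-03T08:00")
        assert compute_lot(course) == 3

    def test_same_day_course_is_one_day(self):
        course = course_between("2020-06-01T08:00", "2020-06-01T20:00")
        assert compute_lot(course) == 1

    def test_overlapping_agents_count_days_once(self):
        rx1 = make_rx(rid="R1", start="2020-06-01T08:00", stop="2020-06-03T10:00")
        rx2 = make_rx(rid="R2", start="2020-06-02T08:00", stop="2020-06-04T18:00")
        (course,) = assemble_courses([rx1, rx2])
        assert compute_lot(course) == 4  # union of covered dates 06-01..06-04


class TestPostDischarge:
    def test_half_post_discharge(self):
        course = course_between("2020-06-01T10:00", "2020-06-10T10:00")
        adm = make_adm(admit="2020-06-01T08:00", discharge="2020-06-05T14:00")
        days, pct = compute_post_discharge(course, adm)
        assert (days, pct) == (5, 50.0)

    def test_course_ending_on_discharge_date(self):
        course = course_between("2020-06-01T10:00", "2020-06-05T10:00")
        adm = make_adm(admit="2020-06-01T08:00", discharge="2020-06-05T14:00")
        assert compute_post_discharge(course, adm) == (0, 0.0)

    def test_course_entirely_after_discharge(self):
        course = course_between("2020-06-08T10:00", "2020-06-10T10:00")
        adm = make_adm(admit="2020-06-01T08:00", discharge="2020-06-05T14:00")
        days, pct = compute_post_discharge(course, adm)
        assert days == compute_lot(course) == 3
        assert pct == 100.0


def _cohort():
    """A hand-built cohort exercising every exclusion reason plus inclusions."""
    label = make_label("targeted", "UTI", "cystitis")
    courses, admissions = [], []

    def add(pid, start, stop, adm_kwargs=None, label_=label, rid="R1"):
        courses.append(course_between(start, stop, pid=pid, label=label_, rid=rid))
        if adm_kwargs is not None:
            admissions.append(make_adm(aid=f"ADM-{pid}", pid=pid, **adm_kwargs))

    # included
    add("P1", "2020-06-01T10:00", "2020-06-06T10:00",
        dict(admit="2020-06-01T08:00", discharge="2020-06-08T10:00"))
    # no admission at all
    add("P2", "2020-06-01T10:00", "2020-06-04T10:00", None)
    # admission under 12 h
    add("P3", "2020-06-01T10:00", "2020-06-03T10:00",
        dict(admit="2020-06-01T08:00", discharge="2020-06-01T18:00"))
    # pediatric
    add("P4", "2020-06-01T10:00", "2020-06-04T10:00",
        dict(admit="2020-06-01T08:00", discharge="2020-06-08T10:00", age=9))
    # ICU during admission
    add("P5", "2020-06-01T10:00", "2020-06-04T10:00",
        dict(admit="2020-06-01T08:00", discharge="2020-06-08T10:00", icu=True))
    # LOT over 45 days
    add("P6", "2020-06-01T10:00", "2020-07-16T10:00",
        dict(admit="2020-06-01T08:00", discharge="2020-06-20T10:00"))
    return courses, admissions


class TestExclusions:
    def test_each_reason_attributed(self):
        courses, admissions = _cohort()
        courses = classify_courses(courses, admissions)
        included, flow = apply_exclusions(courses, admissions)
        assert [c.patient_id for c in included] == ["P1"]
        got = dict((r.value, n) for r, n in flow.steps)
        assert got["not_hospital_initiated"] == 1
        assert got["admission_under_12h"] == 1
        assert got["pediatric"] == 1
        assert got["icu_during_admission"] == 1
        assert got["duration_over_45d"] == 1

    def test_lot_46_excluded_45_included(self):
        label = make_label("targeted", "UTI", "cystitis")
        adm = make_adm(admit="2020-06-01T08:00", discharge="2020-06-20T10:00")
        c45 = course_between("2020-06-01T10:00", "2020-07-15T10:00", label=label)
        c46 = course_between("2020-06-01T10:00", "2020-07-16T10:00", label=label)
        for course, expected in ((c45, None), (c46, ExclusionReason.duration_over_45d)):
            classified = classify_courses([course], [adm])
            _, flow = apply_exclusions(classified, [adm])
            included, _ = apply_exclusions(classified, [adm])
            reason = None if included else ExclusionReason.duration_over_45d
            assert reason == expected

    def test_readmission_mid_course_excluded(self):
        label = make_label("targeted", "UTI", "cystitis")
        course = course_between("2020-06-01T10:00", "2020-06-14T10:00", label=label)
        adms = [
            make_adm(aid="A1", admit="2020-06-01T08:00", discharge="2020-06-05T10:00"),
            make_adm(aid="A2", admit="2020-06-08T09:00", discharge="2020-06-10T10:00"),
        ]
        classified = classify_courses([course], adms)
        included, flow = apply_exclusions(classified, adms)
        assert included == []
        assert dict((r.value, n) for r, n in flow.steps)["readmitted_during_course"] == 1

    def test_short_readmission_does_not_exclude(self):
        # the readmission must itself satisfy the 12 h hospitalization minimum
        label = make_label("targeted", "UTI", "cystitis")
        course = course_between("2020-06-01T10:00", "2020-06-14T10:00", label=label)
        adms = [
            make_adm(aid="A1", admit="2020-06-01T08:00", discharge="2020-06-05T10:00"),
            make_adm(aid="A2", admit="2020-06-08T09:00", discharge="2020-06-08T15:00"),
        ]
        classified = classify_courses([course], adms)
        included, _ = apply_exclusions(classified, adms)
        assert len(included) == 1

    def test_flow_conservation(self):
        courses, admissions = _cohort()
        courses = classify_courses(courses, admissions)
        _, flow = apply_exclusions(courses, admissions)
        assert flow.n_input == flow.n_remaining + sum(n for _, n in flow.steps)

    def test_flow_model_rejects_nonconserved_counts(self):
        with pytest.raises(ValueError, match="conserve"):
            ExclusionFlow(
                steps=[(ExclusionReason.pediatric, 2)], n_input=4, n_remaining=3
            )

    def test_included_set_is_order_invariant(self):
        """Any exclusion ordering yields the same included set; only the
        attribution of overlapping reasons changes."""
        courses, admissions = _cohort()
        courses = classify_courses(courses, admissions)
        baseline, _ = apply_exclusions(courses, admissions)
        base_ids = {c.course_id for c in baseline}
        for perm in itertools.islice(itertools.permutations(EXCLUSION_ORDER), 0, 24, 3):
            included, flow = apply_exclusions(courses, admissions, order=tuple(perm))
            assert {c.course_id for c in included} == base_ids
            assert flow.n_input == flow.n_remaining + sum(n for _, n in flow.steps)

    def test_ca_ha_partition_of_included(self):
        from abxlot.simulate import SimulationConfig, generate
        from abxlot.pipeline import run_pipeline

        res = generate(SimulationConfig(n_patients=200, seed=3))
        result = run_pipeline(res.prescriptions, res.admissions)
        assert all(c.acquisition in ("CA", "HA") for c in result.included)
        assert all(
            0 <= c.post_discharge_days <= c.lot_days for c in result.included
        )
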