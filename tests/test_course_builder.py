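"""Therapeutic filtering, prophylaxis rules and course assembly."""

from datetime import datetime, timedelta

import networkx as nx
import numpy as np
import pytest

from abxlot.config import ProphylaxisRuleSet
from abxlot.courses import (
    assemble_courses,
    effective_stop,
    filter_therapeutic,
    is_presumed_prophylaxis,
    partition_therapeutic,
    resolve_indications,
)

from .conftest import make_label, make_rx


def day_rx(rid, drug, start_day, n_days, dose=100.0, **kw):
    """A prescription running n_days inclusive calendar days from start_day."""
    start = datetime(2020, 6, 1, 9, 0) + timedelta(days=start_day)
    stop = start + timedelta(days=n_days - 1, hours=2)
    return make_rx(
        rid=rid,
        drug=drug,
        atc="J01XX99",
        start=start.isoformat(),
        stop=stop.isoformat(),
        dose=dose,
        **kw,
    )


class TestPresumedProphylaxis:
    @pytest.mark.parametrize(
        "drug,days,dose,expected",
        [
            ("nitrofurantoin", 30, 100, True),
            ("nitrofurantoin", 29, 100, True),
            ("nitrofurantoin", 28, 100, False),  # "more than 28 days" is strict
            ("doxycycline", 40, 100, True),
            ("azithromycin", 28, 500, False),
            ("trimethoprim", 29, 300, True),
            ("trimethoprim/sulfamethoxazole", 15, 480, True),
            ("trimethoprim/sulfamethoxazole", 14, 480, False),
            ("trimethoprim/sulfamethoxazole", 15, 479, True),  # "480 mg or lower"
            ("trimethoprim/sulfamethoxazole", 50, 960, False),
            ("trimethoprim/sulfamethoxazole", 51, 960, True),
            ("trimethoprim/sulfamethoxazole", 15, 481, False),  # high dose, short
            ("co-trimoxazole", 51, 960, True),  # alias spelling
            ("amoxicillin", 40, 1000, False),  # drug not in the rule list
            ("Nitrofurantoin", 30, 100, True),  # case-insensitive drug match
        ],
    )
    def test_rule_boundaries(self, drug, days, dose, expected):
        rx = day_rx("R1", drug, 0, days, dose=dose)
        assert is_presumed_prophylaxis(rx) is expected

    def test_missing_stop_never_presumed(self):
        rx = make_rx(drug="nitrofurantoin", stop=None)
        assert is_presumed_prophylaxis(rx) is False

    def test_ruleset_validation(self):
        with pytest.raises(ValueError):
            ProphylaxisRuleSet(long_term_threshold_days=0)
        with pytest.raises(ValueError):
            ProphylaxisRuleSet(
                cotrimoxazole_low_dose_threshold_days=60,
                cotrimoxazole_high_dose_threshold_days=50,
            )


class TestTherapeuticFilter:
    def test_non_j01_removed(self):
        paracetamol = make_rx(rid="R1", drug="paracetamol", atc="N02BE01")
        kept = filter_therapeutic([paracetamol, make_rx(rid="R2")])
        assert [r.prescription_id for r in kept] == ["R2"]

    def test_labeled_prophylaxis_removed(self):
        prophy = make_rx(rid="R1", label=make_label("prophylaxis", None))
        kept = filter_therapeutic([prophy, make_rx(rid="R2")])
        assert [r.prescription_id for r in kept] == ["R2"]

    def test_presumed_prophylaxis_removed_before_assembly(self):
        trailing = day_rx("R1", "nitrofurantoin", 0, 35)
        kept = filter_therapeutic([trailing])
        assert kept == []

    def test_empty_input(self):
        assert filter_therapeutic([]) == []

    def test_partition_accounts_for_every_record(self):
        records = [
            make_rx(rid="R1"),
            make_rx(rid="R2", atc="N02BE01"),
            make_rx(rid="R3", label=make_label("prophylaxis", None)),
            day_rx("R4", "nitrofurantoin", 0, 40),
        ]
        parts = partition_therapeutic(records)
        assert sum(len(v) for v in parts.values()) == len(records)


class TestEffectiveStop:
    def test_present_stop_is_identity(self):
        rx = make_rx(stop="2020-06-05T10:00")
        assert effective_stop(rx) == datetime(2020, 6, 5, 10, 0)

    def test_missing_stop_truncates_course_to_last_start_date(self):
        rx1 = make_rx(rid="R1", start="2020-06-01T10:00", stop="2020-06-03T10:00")
        rx2 = make_rx(rid="R2", start="2020-06-04T08:00", stop=None)
        (course,) = assemble_courses([rx1, rx2])
        assert course.truncated_missing_stop
        assert course.stop_ts.date() == datetime(2020, 6, 4).date()

    def test_mid_course_missing_stop_gap_from_its_start(self):
        # open-ended rx at 06-02; next rx starts 20 h after its start -> links
        rx1 = make_rx(rid="R1", start="2020-06-02T10:00", stop=None)
        rx2 = make_rx(rid="R2", start="2020-06-03T06:00", stop="2020-06-06T10:00")
        courses = assemble_courses([rx1, rx2])
        assert len(courses) == 1
        assert not courses[0].truncated_missing_stop  # stop came from rx2
        # 25 h after the open-ended start -> separate course
        rx3 = make_rx(rid="R3", start="2020-06-03T11:00", stop="2020-06-06T10:00")
        assert len(assemble_courses([rx1, rx3])) == 2


class TestAssembly:
    def test_gap_under_24h_links(self):
        rx1 = make_rx(rid="R1", start="2020-06-01T10:00", stop="2020-06-05T12:00")
        rx2 = make_rx(rid="R2", start="2020-06-06T10:00", stop="2020-06-08T10:00")
        assert len(assemble_courses([rx1, rx2])) == 1  # 22 h gap

    def test_gap_exactly_24h_links(self):
        rx1 = make_rx(rid="R1", stop="2020-06-05T12:00")
        rx2 = make_rx(rid="R2", start="2020-06-06T12:00", stop="2020-06-08T10:00")
        assert len(assemble_courses([rx1, rx2])) == 1

    def test_gap_over_24h_splits(self):
        rx1 = make_rx(rid="R1", stop="2020-06-05T12:00")
        rx2 = make_rx(rid="R2", start="2020-06-06T12:01", stop="2020-06-08T10:00")
        assert len(assemble_courses([rx1, rx2])) == 2

    def test_single_prescription_course(self):
        (course,) = assemble_courses([make_rx()])
        assert course.start_ts == datetime(2020, 6, 1, 10, 0)
        assert course.stop_ts == datetime(2020, 6, 5, 10, 0)

    def test_three_prescriptions_gaps_10h_then_30h(self):
        rx1 = make_rx(rid="R1", start="2020-06-01T10:00", stop="2020-06-03T10:00")
        rx2 = make_rx(rid="R2", start="2020-06-03T20:00", stop="2020-06-05T10:00")
        rx3 = make_rx(rid="R3", start="2020-06-06T16:00", stop="2020-06-08T10:00")
        courses = assemble_courses([rx1, rx2, rx3])
        memberships = [
            {rx.prescription_id for rx in c.member_prescriptions} for c in courses
        ]
        assert memberships == [{"R1", "R2"}, {"R3"}]

    def test_gap_measured_from_course_frontier_not_previous_rx(self):
        # rx2 nested inside rx1; rx3 starts 20 h after rx1's stop
        rx1 = make_rx(rid="R1", start="2020-06-01T10:00", stop="2020-06-10T10:00")
        rx2 = make_rx(rid="R2", start="2020-06-02T10:00", stop="2020-06-03T10:00")
        rx3 = make_rx(rid="R3", start="2020-06-11T06:00", stop="2020-06-12T10:00")
        assert len(assemble_courses([rx1, rx2, rx3])) == 1

    def test_patients_never_mix(self):
        rx1 = make_rx(rid="R1", pid="P1")
        rx2 = make_rx(rid="R2", pid="P2")
        assert len(assemble_courses([rx1, rx2])) == 2


def _random_patient(rng, n_max=15):
    n = int(rng.integers(1, n_max + 1))
    out = []
    for i in range(n):
        start = datetime(2020, 6, 1) + timedelta(minutes=int(rng.integers(0, 40 * 24 * 60)))
        if rng.random() < 0.15:
            stop = None
        else:
            stop = start + timedelta(minutes=int(rng.integers(0, 10 * 24 * 60)))
        out.append(
            make_rx(
                rid=f"R{i}",
                start=start.isoformat(),
                stop=stop.isoformat() if stop else None,
            )
        )
    return out


def _oracle_partition(prescriptions, gap_hours=24.0):
    """Connected components of the interval graph with edges at gap <= 24 h."""
    gap = timedelta(hours=gap_hours)
    g = nx.Graph()
    g.add_nodes_from(rx.prescription_id for rx in prescriptions)
    for a in prescriptions:
        for b in prescriptions:
            if a.prescription_id >= b.prescription_id:
                continue
            first, second = sorted([a, b], key=lambda r: (r.start_ts, r.prescription_id))
            if second.start_ts <= effective_stop(first) + gap:
                g.add_edge(a.prescription_id, b.prescription_id)
    return {frozenset(c) for c in nx.connected_components(g)}


class TestAssemblyOracle:
    def test_greedy_equals_connected_components(self):
        """Greedy linkage equals brute-force components of the gap graph."""
        rng = np.random.default_rng(42)
        for _ in range(400):
            rxs = _random_patient(rng)
            got = {
                frozenset(rx.prescription_id for rx in c.member_prescriptions)
                for c in assemble_courses(rxs)
            }
            assert got == _oracle_partition(rxs)

    def test_partition_no_loss_no_duplication(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            rxs = _random_patient(rng)
            courses = assemble_courses(rxs)
            ids = [rx.prescription_id for c in courses for rx in c.member_prescriptions]
            assert sorted(ids) == sorted(r.prescription_id for r in rxs)

    def test_idempotence(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            rxs = _random_patient(rng)
            first = assemble_courses(rxs)
            for course in first:
                again = assemble_courses(course.member_prescriptions)
                assert len(again) == 1
                assert again[0].start_ts == course.start_ts
                assert again[0].stop_ts == course.stop_ts

    def test_monotonicity_in_gap(self):
        """Shrinking the gap only refines the partition, never merges."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            rxs = _random_patient(rng)
            wide = assemble_courses(rxs, gap_hours=24.0)
            narrow = assemble_courses(rxs, gap_hours=6.0)
            wide_sets = [
                {rx.prescription_id for rx in c.member_prescriptions} for c in wide
            ]
            for c in narrow:
                ids = {rx.prescription_id for rx in c.member_prescriptions}
                assert any(ids <= w for w in wide_sets)
            assert len(narrow) >= len(wide)


class TestIndicationResolution:
    def test_last_registered_indication_is_definitive(self):
        rx1 = make_rx(rid="R1", label=make_label("empirical", "sepsis e.c.i."))
        rx2 = make_rx(
            rid="R2",
            start="2020-06-03T10:00",
            stop="2020-06-07T10:00",
            label=make_label("targeted", "UTI", "complicated"),
        )
        (course,) = assemble_courses([rx1, rx2])
        course = resolve_indications(course)
        assert course.first_indication.key() == "sepsis e.c.i."
        assert course.definitive_indication.key() == "UTI-complicated"

    def test_single_member_first_equals_definitive(self, therapy_label):
        (course,) = assemble_courses([make_rx(label=therapy_label)])
        course = resolve_indications(course)
        assert course.first_indication == course.definitive_indication == therapy_label

    def test_simultaneous_distinct_final_labels_flagged(self):
        rx1 = make_rx(rid="R1", label=make_label("targeted", "UTI", "cystitis"))
        rx2 = make_rx(rid="R2", label=make_label("targeted", "intra-abdominal"))
        (course,) = assemble_courses([rx1, rx2])
        course = resolve_indications(course)
        assert "multiple_final_diagnoses" in course.exclusion_flags

    def test_simultaneous_same_label_not_flagged(self):
        rx1 = make_rx(rid="R1", label=make_label("empirical", "UTI", "cystitis"))
        rx2 = make_rx(rid="R2", label=make_label("targeted", "UTI", "cystitis"))
        (course,) = assemble_courses([rx1, rx2])
        course = resolve_indications(course)
        assert "multiple_final_diagnoses" not in course.exclusion_flags

    def test_unlabeled_course_flagged_open_text(self):
        (course,) = assemble_courses([make_rx()])
        course = resolve_indications(course)
        assert {"unlabeled", "open_text_indication"} <= course.exclusion_flags

    def test_open_text_member_flags_course(self):
        rx = make_rx(label=make_label("open_text", None, free_text="per note"))
        (course,) = assemble_courses([rx])
        course = resolve_indications(course)
        assert "open_text_indication" in course.exclusion_flags
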