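"""Selection flow, area linkage, follow-up rules, filters and summaries."""

import logging
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clinicplan.cohort import (Concordance, GlobalFilters, PatientRecord,
                               Severity, Sex, StudyWindow, VitalStatus,
                               aggregate_to_areas, apply_global_filters,
                               flag_lost_to_follow_up, link_area,
                               map_diagnoses, read_patients, select_cohort,
                               summarize_cohort, time_since_last_attendance,
                               write_patients)
from clinicplan.geo_model import ValidationError
import clinicplan.cohort as cohort_mod

WINDOW = StudyWindow(date(2000, 1, 1), date(2022, 7, 1))
MID = date(2011, 1, 1)

CONC = Concordance([
    ("2000", "Sydney", "A1", 1.0),
    ("2100", "Split", "A2", 0.7),
    ("2100", "Split", "A3", 0.3),
    ("2200", "Tied", "A5", 0.5),
    ("2200", "Tied", "A4", 0.5),
    ("2300", "NorthTown", "A2", 1.0),
])


def patient(pid="P1", *, dob=date(1980, 1, 1), postcode="2000", suburb="Sydney",
            visits=(MID,), sex=Sex.FEMALE, vital=VitalStatus.ALIVE, dod=None,
            severity=Severity.SIMPLE, diagnoses=()):
    return PatientRecord(patient_id=pid, date_of_birth=dob, sex=sex,
                         vital_status=vital, date_of_death=dod,
                         postcode=postcode, suburb=suburb, state="NSW",
                         diagnoses=list(diagnoses), severity=severity,
                         attendance_dates=list(visits))


class TestLinkArea:
    def test_unique_match(self):
        assert link_area(patient(), CONC) == "A1"

    def test_highest_weight_wins_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            got = link_area(patient(postcode="2100", suburb="Split"), CONC)
        assert got == "A2"
        assert any("ambiguous" in r.message for r in caplog.records)

    def test_equal_weights_take_smaller_area_id(self):
        assert link_area(patient(postcode="2200", suburb="Tied"), CONC) == "A4"

    def test_postcode_fallback_when_suburb_missing(self):
        assert link_area(patient(postcode="2300", suburb=None), CONC) == "A2"

    def test_unresolved_when_no_match(self):
        assert link_area(patient(postcode="9999", suburb="Nowhere"), CONC) is None
        # suburb present but not matching any exact row -> unresolved
        assert link_area(patient(postcode="2000", suburb="Elsewhere"), CONC) is None


class TestSelectCohort:
    def test_age_boundary(self):
        # 18th birthday exactly on the window end: not "under 18", included
        exactly_18 = patient("p18", dob=WINDOW.end.replace(year=WINDOW.end.year - 18))
        one_day_younger = patient(
            "p17", dob=WINDOW.end.replace(year=WINDOW.end.year - 18) + timedelta(days=1))
        cohort, flow = select_cohort([exactly_18, one_day_younger], WINDOW, CONC)
        assert [p.patient_id for p in cohort] == ["p18"]
        assert flow.excluded_under_18 == 1

    def test_first_match_exclusion_order_and_conservation(self):
        records = [
            patient("ok1"), patient("ok2"), patient("ok3"),
            patient("ok4"), patient("ok5"), patient("ok6"),
            patient("minor1", dob=date(2010, 1, 1)),
            # minor with a bad address too: counted at the age stage
            patient("minor2", dob=date(2010, 1, 1), postcode="9999"),
            patient("badaddr", postcode="9999"),
            patient("oow", visits=[date(1999, 1, 1)]),
        ]
        cohort, flow = select_cohort(records, WINDOW, CONC)
        assert flow.input_total == 10
        assert flow.excluded_under_18 == 2
        assert flow.excluded_no_valid_address == 1
        assert flow.excluded_no_encounter_in_window == 1
        assert flow.included == len(cohort) == 6
        assert all(p.area_id == "A1" for p in cohort)

    def test_empty_input_gives_zeroed_flow(self):
        cohort, flow = select_cohort([], WINDOW, CONC)
        assert len(cohort) == 0 and flow.input_total == 0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(5, 80),       # age at window end
                              st.booleans(),            # address resolvable
                              st.booleans()),           # has in-window visit
                    max_size=40))
    def test_flow_conservation_property(self, specs):
        records = []
        for i, (age, good_addr, in_window) in enumerate(specs):
            records.append(patient(
                f"p{i}",
                dob=WINDOW.end - timedelta(days=round(age * 365.25) + 1),
                postcode="2000" if good_addr else "9999",
                suburb="Sydney" if good_addr else "Nowhere",
                visits=[MID if in_window else date(1998, 5, 5)]))
        _, flow = select_cohort(records, WINDOW, CONC)
        assert (flow.included + flow.excluded_under_18 + flow.excluded_no_valid_address
                + flow.excluded_no_encounter_in_window) == flow.input_total == len(specs)


class TestFollowUp:
    def test_last_visit_at_window_end_is_zero(self):
        assert time_since_last_attendance(patient(visits=[WINDOW.end]), WINDOW) == 0.0

    def test_three_year_gap_alive(self):
        p = patient(visits=[date(2019, 7, 1)])
        assert time_since_last_attendance(p, WINDOW) == pytest.approx(3.0, abs=0.01)

    def test_death_date_is_the_reference_for_deceased(self):
        p = patient(vital=VitalStatus.DECEASED, dod=date(2015, 1, 1),
                    visits=[date(2014, 1, 1)])
        assert time_since_last_attendance(p, WINDOW) == pytest.approx(1.0, abs=0.01)
        # a short gap to death is not lost to follow-up even though the death
        # was many years before the window end
        assert not flag_lost_to_follow_up(p, WINDOW)

    def test_visit_after_reference_clamps_to_zero(self, caplog):
        p = patient(vital=VitalStatus.DECEASED, dod=date(2015, 1, 1),
                    visits=[date(2016, 1, 1)])
        with caplog.at_level(logging.WARNING):
            assert time_since_last_attendance(p, WINDOW) == 0.0
        assert any("clamped" in r.message for r in caplog.records)

    def test_no_attendance_is_contract_violation(self):
        with pytest.raises(ValidationError):
            time_since_last_attendance(patient(visits=[]), WINDOW)

    def test_ltf_threshold_is_strict(self, monkeypatch):
        p = patient()
        monkeypatch.setattr(cohort_mod, "time_since_last_attendance",
                            lambda pat, win: 3.0)
        assert flag_lost_to_follow_up(p, WINDOW) is False
        monkeypatch.setattr(cohort_mod, "time_since_last_attendance",
                            lambda pat, win: 3.0001)
        assert flag_lost_to_follow_up(p, WINDOW) is True

    def test_five_year_gap_is_lost(self):
        assert flag_lost_to_follow_up(patient(visits=[date(2017, 6, 1)]), WINDOW)


class TestMapDiagnoses:
    TABLE = {"c1": "Tetralogy of Fallot", "c2": "Atrial Septal Defect",
             "c3": "Tetralogy of Fallot"}

    def test_mapping_and_unmapped(self, caplog):
        p = patient(diagnoses=["c1", "weird"])
        with caplog.at_level(logging.WARNING):
            labels = map_diagnoses(p, self.TABLE)
        assert labels == ["Tetralogy of Fallot", "Unmapped"]
        assert any("weird" in r.message for r in caplog.records)

    def test_two_codes_one_label_deduplicated(self):
        assert map_diagnoses(patient(diagnoses=["c1", "c3"]), self.TABLE) == \
            ["Tetralogy of Fallot"]


class TestGlobalFilters:
    def _cohort(self):
        records = [patient(f"p{i}", severity=s, sex=sex, vital=v, dod=dod)
                   for i, (s, sex, v, dod) in enumerate([
                       (Severity.COMPLEX, Sex.FEMALE, VitalStatus.ALIVE, None),
                       (Severity.COMPLEX, Sex.MALE, VitalStatus.ALIVE, None),
                       (Severity.COMPLEX, Sex.MALE, VitalStatus.DECEASED, date(2012, 1, 1)),
                       (Severity.SIMPLE, Sex.FEMALE, VitalStatus.ALIVE, None),
                       (Severity.MODERATE, Sex.MALE, VitalStatus.ALIVE, None),
                   ])]
        cohort, _ = select_cohort(records, WINDOW, CONC)
        return cohort

    def test_inactive_filters_are_identity(self):
        cohort = self._cohort()
        assert len(apply_global_filters(cohort, GlobalFilters(), WINDOW)) == len(cohort)

    def test_severity_subset(self):
        got = apply_global_filters(self._cohort(),
                                   GlobalFilters(severities=frozenset({Severity.COMPLEX})),
                                   WINDOW)
        assert len(got) == 3

    def test_alive_only_excludes_deceased(self):
        got = apply_global_filters(
            self._cohort(),
            GlobalFilters(vital_statuses=frozenset({VitalStatus.ALIVE})), WINDOW)
        assert all(p.vital_status == VitalStatus.ALIVE for p in got)
        assert len(got) == 4

    def test_contradictory_age_range_rejected(self):
        with pytest.raises(ValidationError):
            GlobalFilters(age_min=50, age_max=20)

    def test_composition_equals_conjunction_and_never_grows(self):
        cohort = self._cohort()
        f1 = GlobalFilters(severities=frozenset({Severity.COMPLEX}))
        f2 = GlobalFilters(sexes=frozenset({Sex.MALE}))
        both = GlobalFilters(severities=frozenset({Severity.COMPLEX}),
                             sexes=frozenset({Sex.MALE}))
        step = apply_global_filters(apply_global_filters(cohort, f1, WINDOW), f2, WINDOW)
        joint = apply_global_filters(cohort, both, WINDOW)
        assert [p.patient_id for p in step] == [p.patient_id for p in joint]
        assert len(joint) <= len(cohort)


class TestAggregation:
    def test_counts_and_conservation(self, tiny_areas):
        records = ([patient(f"a{i}") for i in range(5)]
                   + [patient(f"b{i}", postcode="2300", suburb=None,
                              severity=Severity.COMPLEX) for i in range(3)])
        cohort, _ = select_cohort(records, WINDOW, CONC)
        aggs = aggregate_to_areas(cohort, tiny_areas, WINDOW)
        by_id = {a.area_id: a for a in aggs}
        assert len(aggs) == len(tiny_areas)  # zero aggregates included
        assert by_id["A1"].n_patients == 5
        assert by_id["A2"].n_patients == 3
        assert by_id["A3"].n_patients == 0
        assert sum(a.n_patients for a in aggs) == len(cohort)
        for a in aggs:
            assert sum(a.n_by_severity.values()) == a.n_patients
            assert a.n_lost_to_follow_up <= a.n_patients

    def test_unknown_area_is_hard_error(self, tiny_areas):
        cohort, _ = select_cohort([patient("py")], WINDOW, CONC)
        cohort[0].area_id = "A999"
        with pytest.raises(ValidationError, match="py"):
            aggregate_to_areas(cohort, tiny_areas, WINDOW)


class TestSummarize:
    def test_single_patient_moments(self):
        p = patient(dob=WINDOW.end - timedelta(days=round(40 * 365.25)))
        cohort, _ = select_cohort([p], WINDOW, CONC)
        s = summarize_cohort(cohort, WINDOW)
        assert s.overall.n == 1
        assert s.overall.age_mean == pytest.approx(40.0, abs=0.01)
        assert s.overall.age_sd is None  # undefined, reported missing
        assert s.overall.pct_female == 100.0

    def test_stratum_ns_sum_to_overall(self):
        records = [patient(f"p{i}", severity=list(Severity)[i % 4]) for i in range(13)]
        cohort, _ = select_cohort(records, WINDOW, CONC)
        s = summarize_cohort(cohort, WINDOW)
        assert sum(st.n for st in s.by_severity.values()) == s.overall.n == 13

    def test_empty_cohort_reports_missing(self):
        s = summarize_cohort(cohort_mod.Cohort([]), WINDOW)
        assert s.overall.n == 0
        assert s.overall.age_mean is None
        assert s.overall.pct_female is None


class TestPatientCsvRoundTrip:
    def test_round_trip(self, tmp_path):
        records = [
            patient("p1", diagnoses=["c1", "c2"], visits=[MID, date(2015, 3, 2)]),
            patient("p2", vital=VitalStatus.DECEASED, dod=date(2010, 5, 1),
                    visits=[date(2009, 1, 1)], sex=Sex.MALE),
        ]
        path = tmp_path / "patients.csv"
        write_patients(records, path)
        back = read_patients(path)
        assert back == records
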