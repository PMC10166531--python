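"""Nearest-clinic engine vs a brute-force oracle, coverage statistics,
clinic reach, and candidate evaluation."""

import numpy as np
import pytest

from clinicplan.accessibility import (accessibility_summary, clinic_reach,
                                      drive_time_layer, evaluate_candidates,
                                      nearest_clinic_time)
from clinicplan.cohort import AreaAggregate
from clinicplan.geo_model import (Area, AreaSet, ClinicSet, Region,
                                  TravelTimeMatrix, ValidationError)

from conftest import brute_force_nearest, make_world


def _areas(*specs):
    return AreaSet([Area(aid, aid, region) for aid, region in specs])


def _aggs(counts, ltf=None):
    ltf = ltf or {}
    return [AreaAggregate(area_id=a, n_patients=n,
                          n_lost_to_follow_up=ltf.get(a, 0))
            for a, n in counts.items()]


class TestNearestClinic:
    def test_single_clinic(self):
        ttm = TravelTimeMatrix({("A1", "H1"): 0.5})
        acc = nearest_clinic_time("A1", ClinicSet(["H1"]), ttm)
        assert (acc.nearest_facility_id, acc.nearest_time) == ("H1", 0.5)

    def test_minimum_over_clinics(self):
        ttm = TravelTimeMatrix({("A1", "H1"): 1.2, ("A1", "H2"): 0.9})
        acc = nearest_clinic_time("A1", ClinicSet(["H1", "H2"]), ttm)
        assert (acc.nearest_facility_id, acc.nearest_time) == ("H2", 0.9)

    def test_tie_breaks_to_smaller_facility_id(self):
        ttm = TravelTimeMatrix({("A1", "H2"): 0.7, ("A1", "H1"): 0.7})
        acc = nearest_clinic_time("A1", ClinicSet(["H2", "H1"]), ttm)
        assert acc.nearest_facility_id == "H1"

    def test_uncovered_area(self):
        ttm = TravelTimeMatrix({("A1", "H1"): 0.5})
        acc = nearest_clinic_time("A2", ClinicSet(["H1"]), ttm)
        assert acc.uncovered and acc.nearest_facility_id is None

    def test_empty_clinic_set_rejected(self):
        with pytest.raises(ValidationError):
            nearest_clinic_time("A1", ClinicSet([]), TravelTimeMatrix({}))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        areas, fids, ttm, _ = make_world(rng, max_areas=20, max_facilities=6,
                                         pair_missing_p=0.2)
        clinics = ClinicSet(fids)
        for a in areas:
            got = nearest_clinic_time(a.area_id, clinics, ttm)
            fid, t = brute_force_nearest(a.area_id, clinics, ttm)
            assert (got.nearest_facility_id, got.nearest_time) == (fid, t)


class TestAccessibilitySummary:
    def test_all_areas_at_zero(self):
        areas = _areas(("A1", Region.GREATER_SYDNEY))
        ttm = TravelTimeMatrix({("A1", "H1"): 0.0})
        s = accessibility_summary(_aggs({"A1": 4}), ClinicSet(["H1"]), ttm,
                                  1.0, "All", areas)
        assert (s.pct_within_threshold, s.mean_time, s.max_time) == (100.0, 0.0, 0.0)

    def test_hand_computed_weighted_example(self):
        # areas with (patients, hours) = (2, 0.5), (3, 1.2), (5, 2.0)
        areas = _areas(("A1", Region.REST_OF_STATE), ("A2", Region.REST_OF_STATE),
                       ("A3", Region.REST_OF_STATE))
        ttm = TravelTimeMatrix({("A1", "H1"): 0.5, ("A2", "H1"): 1.2, ("A3", "H1"): 2.0})
        s = accessibility_summary(_aggs({"A1": 2, "A2": 3, "A3": 5}),
                                  ClinicSet(["H1"]), ttm, 1.0, "All", areas)
        assert s.pct_within_threshold == pytest.approx(20.0)
        assert s.mean_time == pytest.approx(1.46)
        assert s.max_time == pytest.approx(2.0)

    def test_threshold_is_strict_but_epsilon_above_includes(self):
        areas = _areas(("A1", Region.ACT))
        ttm = TravelTimeMatrix({("A1", "H1"): 1.0})
        aggs = _aggs({"A1": 7})
        at = accessibility_summary(aggs, ClinicSet(["H1"]), ttm, 1.0, "All", areas)
        above = accessibility_summary(aggs, ClinicSet(["H1"]), ttm, 1.0 + 1e-9,
                                      "All", areas)
        assert at.n_within_threshold == 0
        assert above.n_within_threshold == 7

    def test_uncovered_patients_reported_separately(self):
        areas = _areas(("A1", Region.ACT), ("A2", Region.ACT))
        ttm = TravelTimeMatrix({("A1", "H1"): 0.5})
        s = accessibility_summary(_aggs({"A1": 3, "A2": 4}), ClinicSet(["H1"]),
                                  ttm, 1.0, "All", areas)
        assert s.n_patients_uncovered == 4
        assert s.n_patients_covered == 3
        assert s.pct_within_threshold == 100.0  # of covered patients only

    def test_zero_covered_patients_reports_missing(self):
        areas = _areas(("A1", Region.ACT))
        s = accessibility_summary(_aggs({"A1": 3}), ClinicSet(["H1"]),
                                  TravelTimeMatrix({}), 1.0, "All", areas)
        assert s.pct_within_threshold is None
        assert s.mean_time is None and s.max_time is None

    @pytest.mark.parametrize("seed", range(5))
    def test_scope_means_combine_to_all_scope_mean(self, seed):
        rng = np.random.default_rng(100 + seed)
        areas, fids, ttm, aggs = make_world(rng)
        clinics = ClinicSet(fids)
        total = accessibility_summary(aggs, clinics, ttm, 1.0, "All", areas)
        covered_sum = 0.0
        covered_n = 0
        for region in Region:
            s = accessibility_summary(aggs, clinics, ttm, 1.0, region.value, areas)
            if s.mean_time is not None:
                covered_sum += s.mean_time * s.n_patients_covered
                covered_n += s.n_patients_covered
        if covered_n:
            assert total.mean_time == pytest.approx(covered_sum / covered_n)
            assert total.n_patients_covered == covered_n


class TestClinicReach:
    def test_single_area_within(self):
        ttm = TravelTimeMatrix({("A1", "H1"): 0.4})
        row = clinic_reach("H1", _aggs({"A1": 10}, ltf={"A1": 3}), ttm, 1.0)
        assert (row.n_patients_within_threshold, row.n_ltf_within_threshold) == (10, 3)

    def test_exactly_at_threshold_is_outside(self):
        ttm = TravelTimeMatrix({("A1", "H1"): 1.0})
        row = clinic_reach("H1", _aggs({"A1": 10}, ltf={"A1": 3}), ttm, 1.0)
        assert (row.n_patients_within_threshold, row.n_ltf_within_threshold) == (0, 0)

    def test_rows_overlap_across_clinics(self):
        ttm = TravelTimeMatrix({("A1", "H1"): 0.3, ("A1", "H2"): 0.6})
        aggs = _aggs({"A1": 8}, ltf={"A1": 2})
        r1 = clinic_reach("H1", aggs, ttm, 1.0)
        r2 = clinic_reach("H2", aggs, ttm, 1.0)
        assert r1.n_patients_within_threshold == r2.n_patients_within_threshold == 8

    def test_facility_without_data_warns_and_zeroes(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            row = clinic_reach("H9", _aggs({"A1": 5}), TravelTimeMatrix({("A1", "H1"): 0.2}))
        assert row.n_patients_within_threshold == 0
        assert any("H9" in r.message for r in caplog.records)


class TestEvaluateCandidates:
    def test_no_candidates_means_zero_deltas(self):
        areas = _areas(("A1", Region.ACT))
        ttm = TravelTimeMatrix({("A1", "H1"): 0.5})
        comp = evaluate_candidates(ClinicSet(["H1"]), ClinicSet([]),
                                   _aggs({"A1": 5}), ttm, 1.0, areas)
        assert all(v == 0 for v in comp.delta_patients_within.values())
        assert all(not v for v in comp.delta_mean_time.values())

    def test_overlap_rejected(self):
        areas = _areas(("A1", Region.ACT))
        ttm = TravelTimeMatrix({("A1", "H1"): 0.5})
        with pytest.raises(ValidationError):
            evaluate_candidates(ClinicSet(["H1"]), ClinicSet(["H1"]),
                                _aggs({"A1": 5}), ttm, 1.0, areas)

    def test_clinic_in_worst_area_strictly_improves(self):
        areas = _areas(("A1", Region.REST_OF_STATE), ("A2", Region.REST_OF_STATE))
        ttm = TravelTimeMatrix({("A1", "H1"): 0.2, ("A2", "H1"): 3.0,
                                ("A1", "H2"): 3.0, ("A2", "H2"): 0.1})
        comp = evaluate_candidates(ClinicSet(["H1"]), ClinicSet(["H2"]),
                                   _aggs({"A1": 5, "A2": 5}), ttm, 1.0, areas)
        b, a = comp.before["All"], comp.after["All"]
        assert a.pct_within_threshold > b.pct_within_threshold
        assert a.max_time < b.max_time

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_in_the_clinic_set(self, seed):
        rng = np.random.default_rng(200 + seed)
        areas, fids, ttm, aggs = make_world(rng)
        if len(fids) < 2:
            fids = fids + ["Fxx"]
        k = int(rng.integers(1, len(fids)))
        current, candidates = ClinicSet(fids[:k]), ClinicSet(fids[k:])
        comp = evaluate_candidates(current, candidates, aggs, ttm, 1.0, areas)
        for scope in comp.before:
            b, a = comp.before[scope], comp.after[scope]
            assert a.n_within_threshold >= b.n_within_threshold
            if b.mean_time is not None and a.mean_time is not None:
                assert a.mean_time <= b.mean_time + 1e-12
            if b.max_time is not None and a.max_time is not None:
                assert a.max_time <= b.max_time + 1e-12


class TestDriveTimeLayer:
    def test_numbers_and_uncovered(self):
        areas = _areas(("A1", Region.ACT), ("A2", Region.ACT), ("A3", Region.ACT))
        ttm = TravelTimeMatrix({("A1", "H1"): 0.5, ("A2", "H1"): 1.5})
        layer = drive_time_layer(ClinicSet(["H1"]), ttm, areas)
        assert layer == {"A1": 0.5, "A2": 1.5, "A3": None}

    @pytest.mark.parametrize("seed", range(5))
    def test_layer_equals_oracle_and_adding_clinics_never_raises_values(self, seed):
        rng = np.random.default_rng(300 + seed)
        areas, fids, ttm, _ = make_world(rng)
        clinics = ClinicSet(fids[: max(1, len(fids) // 2)])
        layer = drive_time_layer(clinics, ttm, areas)
        for aid, val in layer.items():
            assert val == brute_force_nearest(aid, clinics, ttm)[1]
        bigger = drive_time_layer(ClinicSet(fids), ttm, areas)
        for aid in layer:
            if layer[aid] is not None:
                assert bigger[aid] is not None and bigger[aid] <= layer[aid]
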