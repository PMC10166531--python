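"""Nearest-clinic drive-time engine and patient-weighted coverage summaries.

Every patient inherits the driving time of their residential area to the
nearest open clinic.  Coverage ("within a 1-hour drive") is strict:
an area at exactly the threshold is *not* within it.  Areas with no
travel-time data are "uncovered"; their patients are excluded from the
percentage/mean/maximum statistics and reported as a separate count —
missing data is never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .geo_model import AreaSet, ClinicSet, Region, TravelTimeMatrix, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_HOURS = 1.0


@dataclass(frozen=True)
class AreaAccess:
    """Nearest open clinic for one area, or uncovered when no data exists."""

    area_id: str
    nearest_facility_id: Optional[str]
    nearest_time: Optional[float]  # hours; None = uncovered

    @property
    def uncovered(self) -> bool:
        return self.nearest_time is None


@dataclass
class AccessibilitySummary:
    """Patient-weighted coverage statistics for one scope (region or All)."""

    scope: str  # "All" or a Region value
    threshold: float
    n_patients_in_scope: int
    n_patients_covered: int
    n_patients_uncovered: int
    n_within_threshold: int
    pct_within_threshold: Optional[float]  # of covered patients; None if none
    mean_time: Optional[float]  # patient-weighted, hours
    max_time: Optional[float]   # over areas holding >=1 in-scope patient


@dataclass(frozen=True)
class ClinicTableRow:
    """Patients (and lost-to-follow-up patients) within reach of ONE clinic.

    Reach is independent of other clinics, so rows overlap: a patient within
    the threshold of two clinics is counted in both rows.
    """

    facility_id: str
    n_patients_within_threshold: int
    n_ltf_within_threshold: int


@dataclass
class CandidateComparison:
    """Before/after summaries per scope for a candidate clinic set."""

    before: dict[str, AccessibilitySummary]
    after: dict[str, AccessibilitySummary]
    delta_patients_within: dict[str, int]
    delta_mean_time: dict[str, Optional[float]]
    delta_max_time: dict[str, Optional[float]]


def nearest_clinic_time(area_id: str, clinics: ClinicSet,
                        ttm: TravelTimeMatrix) -> AreaAccess:
    """Minimum driving time from an area over the open clinic set.

    Ties go to the lexicographically smallest facility id.  Returns an
    uncovered AreaAccess when the area has no matrix entry for any clinic.
    """
    if len(clinics) == 0:
        raise ValidationError("nearest_clinic_time requires a non-empty clinic set")
    best_fid: Optional[str] = None
    best_time: Optional[float] = None
    for fid in clinics:
        t = ttm.lookup(area_id, fid)
        if t is None:
            continue
        if best_time is None or t < best_time or (t == best_time and fid < best_fid):
            best_fid, best_time = fid, t
    return AreaAccess(area_id=area_id, nearest_facility_id=best_fid, nearest_time=best_time)


def drive_time_layer(clinics: ClinicSet, ttm: TravelTimeMatrix,
                     areas: AreaSet) -> dict[str, Optional[float]]:
    """Per-area nearest-clinic time for the choropleth; ``None`` = uncovered."""
    return {a.area_id: nearest_clinic_time(a.area_id, clinics, ttm).nearest_time
            for a in areas}


def _scope_region(scope: str) -> Optional[Region]:
    if scope == "All":
        return None
    return Region(scope)


def accessibility_summary(aggregates: Sequence, clinics: ClinicSet,
                          ttm: TravelTimeMatrix, threshold_hours: float,
                          scope: str, areas: AreaSet) -> AccessibilitySummary:
    """Patient-weighted coverage statistics for one scope.

    Each patient inherits their area's nearest-clinic time.  The percentage
    within the threshold is over *covered* patients (strict ``<``); the mean
    is the patient-count-weighted mean of area times; the maximum is over
    areas containing at least one in-scope patient.  Patients in uncovered
    areas are excluded from all three and reported separately.
    """
    if threshold_hours <= 0:
        raise ValidationError("threshold must be positive")
    region = _scope_region(scope)
    scoped_ids = {a.area_id for a in areas.in_region(region)}

    n_in_scope = n_covered = n_uncovered = n_within = 0
    weighted_time_sum = 0.0
    max_time: Optional[float] = None
    for agg in aggregates:
        if agg.area_id not in scoped_ids:
            continue
        n = int(agg.n_patients)
        if n == 0:
            continue
        n_in_scope += n
        access = nearest_clinic_time(agg.area_id, clinics, ttm)
        if access.uncovered:
            n_uncovered += n
            continue
        t = access.nearest_time
        n_covered += n
        weighted_time_sum += n * t
        if t < threshold_hours:
            n_within += n
        if max_time is None or t > max_time:
            max_time = t
    if n_covered == 0:
        return AccessibilitySummary(scope=scope, threshold=threshold_hours,
                                    n_patients_in_scope=n_in_scope,
                                    n_patients_covered=0, n_patients_uncovered=n_uncovered,
                                    n_within_threshold=0, pct_within_threshold=None,
                                    mean_time=None, max_time=None)
    return AccessibilitySummary(
        scope=scope, threshold=threshold_hours,
        n_patients_in_scope=n_in_scope,
        n_patients_covered=n_covered,
        n_patients_uncovered=n_uncovered,
        n_within_threshold=n_within,
        pct_within_threshold=100.0 * n_within / n_covered,
        mean_time=weighted_time_sum / n_covered,
        max_time=max_time,
    )


def clinic_reach(facility_id: str, aggregates: Sequence, ttm: TravelTimeMatrix,
                 threshold_hours: float = DEFAULT_THRESHOLD_HOURS) -> ClinicTableRow:
    """Patients (total and lost-to-follow-up) within direct reach of one clinic.

    Sums area counts over areas whose direct time to THIS facility is
    strictly below the threshold; independent of every other clinic.
    """
    n_patients = 0
    n_ltf = 0
    any_entry = False
    for agg in aggregates:
        t = ttm.lookup(agg.area_id, facility_id)
        if t is None:
            continue
        any_entry = True
        if t < threshold_hours:
            n_patients += int(agg.n_patients)
            n_ltf += int(agg.n_lost_to_follow_up)
    if not any_entry:
        logger.warning("facility %s has no travel-time data; reach reported as zero",
                       facility_id)
    return ClinicTableRow(facility_id=facility_id,
                          n_patients_within_threshold=n_patients,
                          n_ltf_within_threshold=n_ltf)


ALL_SCOPES = ("All", Region.GREATER_SYDNEY.value, Region.ACT.value,
              Region.REST_OF_STATE.value)


def evaluate_candidates(current: ClinicSet, candidates: ClinicSet,
                        aggregates: Sequence, ttm: TravelTimeMatrix,
                        threshold_hours: float, areas: AreaSet,
                        scopes: Sequence[str] = ALL_SCOPES) -> CandidateComparison:
    """Before/after accessibility comparison for a candidate clinic set.

    ``candidates`` must be disjoint from ``current``.  Adding clinics can
    only shrink nearest times, so per-scope mean and max never increase and
    coverage never decreases.
    """
    overlap = [f for f in candidates if f in current]
    if overlap:
        raise ValidationError(f"candidate clinics already open: {overlap}")
    combined = current.union(candidates)
    before = {s: accessibility_summary(aggregates, current, ttm, threshold_hours, s, areas)
              for s in scopes}
    after = {s: accessibility_summary(aggregates, combined, ttm, threshold_hours, s, areas)
             for s in scopes}

    def _delta(f_after: Optional[float], f_before: Optional[float]) -> Optional[float]:
        if f_after is None or f_before is None:
            return None
        return f_after - f_before

    return CandidateComparison(
        before=before, after=after,
        delta_patients_within={s: after[s].n_within_threshold - before[s].n_within_threshold
                               for s in scopes},
        delta_mean_time={s: _delta(after[s].mean_time, before[s].mean_time) for s in scopes},
        delta_max_time={s: _delta(after[s].max_time, before[s].max_time) for s in scopes},
    )


def rank_candidate_hospitals(facilities: Mapping, current: ClinicSet,
                             aggregates: Sequence, ttm: TravelTimeMatrix,
                             areas: AreaSet, k: int = 3,
                             region: Optional[Region] = Region.REST_OF_STATE,
                             ) -> ClinicSet:
    """Pick k candidate hospitals serving the worst-served areas, greedily.

    A reproducible stand-in for a planner hand-picking rural hospitals off
    the map: at each step, find the covered patient-bearing area in the
    given region with the longest current nearest-clinic time, and open the
    eligible hospital (role ``hospital``, not already open) that is closest
    to it — provided that strictly improves the area.  This is a
    demonstration heuristic, not facility-location optimisation.
    """
    from .geo_model import FacilityRole

    counts = {agg.area_id: int(agg.n_patients) for agg in aggregates}
    region_ids = {a.area_id for a in areas.in_region(region)}
    eligible = {fid for fid, fac in facilities.items()
                if fac.role == FacilityRole.HOSPITAL and fid not in current}
    working = ClinicSet(list(current))
    chosen: list[str] = []
    for _ in range(k):
        ranked: list[tuple[float, str]] = []
        for aid in region_ids:
            if counts.get(aid, 0) == 0:
                continue
            access = nearest_clinic_time(aid, working, ttm)
            if not access.uncovered:
                ranked.append((access.nearest_time, aid))
        ranked.sort(key=lambda s: (-s[0], s[1]))
        pick: Optional[str] = None
        for worst_t, aid in ranked:
            options = [(t, fid) for fid in sorted(eligible)
                       if (t := ttm.lookup(aid, fid)) is not None and t < worst_t]
            if options:
                pick = min(options)[1]
                break
        if pick is None:
            break
        chosen.append(pick)
        eligible.discard(pick)
        working = working.union(ClinicSet([pick]))
    return ClinicSet(chosen)
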