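"""Patient cohort selection, area linkage, filtering and aggregation.

Implements the study's patient-selection flow: start from the raw clinic
database extract, drop patients under 18 at the end of the study window,
drop patients whose postcode/suburb cannot be linked to an in-scope
statistical area, and drop patients with no clinic attendance inside the
window.  Exclusions are counted first-match in the fixed order
age -> address -> encounter.

Follow-up is referenced to the end of the study window for living patients
and to the date of death for deceased patients; a gap strictly longer than
three years marks a patient as lost to follow-up.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np

from .geo_model import AreaSet, ValidationError

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25
LTF_THRESHOLD_YEARS = 3.0  # "gap in care longer than three years"
ADULT_AGE_YEARS = 18


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"
    OTHER_UNKNOWN = "other/unknown"


class VitalStatus(str, Enum):
    ALIVE = "alive"
    DECEASED = "deceased"


class Severity(str, Enum):
    """Clinician-assigned anatomic complexity (an input field, not computed)."""

    SIMPLE = "Simple"
    MODERATE = "Moderate"
    COMPLEX = "Complex"
    UNKNOWN = "Unknown"


UNRESOLVED = None  # link_area result for an address that cannot be linked


@dataclass
class PatientRecord:
    patient_id: str
    date_of_birth: date
    sex: Sex = Sex.OTHER_UNKNOWN
    vital_status: VitalStatus = VitalStatus.ALIVE
    date_of_death: Optional[date] = None
    postcode: Optional[str] = None
    suburb: Optional[str] = None
    state: Optional[str] = None
    area_id: Optional[str] = None
    diagnoses: list[str] = field(default_factory=list)
    severity: Severity = Severity.UNKNOWN
    attendance_dates: list[date] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.vital_status == VitalStatus.DECEASED) != (self.date_of_death is not None):
            raise ValidationError(
                f"patient {self.patient_id!r}: date_of_death must be present "
                f"iff vital_status is deceased"
            )
        self.attendance_dates = sorted(self.attendance_dates)

    def age_at(self, ref: date) -> float:
        return (ref - self.date_of_birth).days / DAYS_PER_YEAR

    def calendar_age_at(self, ref: date) -> int:
        """Completed years of age at ``ref`` (birthday-based, like an ID check)."""
        dob = self.date_of_birth
        return ref.year - dob.year - ((ref.month, ref.day) < (dob.month, dob.day))


@dataclass(frozen=True)
class StudyWindow:
    start: date
    end: date

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"study window start {self.start} must precede end {self.end}")

    def contains(self, d: date) -> bool:
        return self.start <= d <= self.end


@dataclass
class SelectionFlow:
    """Counts at each stage of the patient-selection flowchart."""

    input_total: int = 0
    excluded_under_18: int = 0
    excluded_no_valid_address: int = 0
    excluded_no_encounter_in_window: int = 0
    included: int = 0
    included_alive: int = 0

    def check(self) -> None:
        total = (self.included + self.excluded_under_18
                 + self.excluded_no_valid_address + self.excluded_no_encounter_in_window)
        if total != self.input_total:
            raise AssertionError(f"selection flow does not conserve: {self}")
        if self.included_alive > self.included:
            raise AssertionError(f"included_alive exceeds included: {self}")


class Cohort:
    """The filtered study population (ordered, unique patient ids)."""

    def __init__(self, patients: Iterable[PatientRecord]):
        self._patients = list(patients)

    def __len__(self) -> int:
        return len(self._patients)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self._patients)

    def __getitem__(self, i: int) -> PatientRecord:
        return self._patients[i]

    @property
    def patients(self) -> list[PatientRecord]:
        return list(self._patients)


# ---------------------------------------------------------------------------
# Concordance and area linkage
# ---------------------------------------------------------------------------

class Concordance:
    """Postcode/suburb -> area lookup with population weights."""

    def __init__(self, rows: Iterable[tuple[str, str, str, float]]):
        # rows: (postcode, suburb, area_id, weight)
        self._exact: dict[tuple[str, str], list[tuple[str, float]]] = {}
        self._by_postcode: dict[str, list[tuple[str, float]]] = {}
        for postcode, suburb, area_id, weight in rows:
            key = (str(postcode).strip(), str(suburb).strip().lower())
            self._exact.setdefault(key, []).append((area_id, float(weight)))
            self._by_postcode.setdefault(key[0], []).append((area_id, float(weight)))

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "Concordance":
        rows = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                rows.append((row["postcode"], row["suburb"], row["area_id"],
                             float(row.get("weight", 1.0) or 1.0)))
        return cls(rows)

    def candidates(self, postcode: str, suburb: Optional[str]) -> list[tuple[str, float]]:
        if suburb is not None and suburb.strip():
            return self._exact.get((postcode.strip(), suburb.strip().lower()), [])
        return self._by_postcode.get(postcode.strip(), [])


def link_area(patient: PatientRecord, concordance: Concordance) -> Optional[str]:
    """Resolve a patient's postcode/suburb to an area id.

    An exact (postcode, suburb) match wins; among multiple matching rows the
    highest weight wins, ties broken by lexicographically smallest area id
    (logged as ambiguous).  When the suburb is missing, a postcode-only
    lookup is used.  Returns ``None`` (unresolved) when nothing matches.
    """
    if not patient.postcode or not str(patient.postcode).strip():
        return UNRESOLVED
    rows = concordance.candidates(str(patient.postcode), patient.suburb)
    if not rows:
        return UNRESOLVED
    if len(rows) > 1:
        logger.warning(
            "ambiguous area linkage for patient %s (postcode=%s suburb=%s): %d candidates",
            patient.patient_id, patient.postcode, patient.suburb, len(rows))
    # highest weight first, then smallest area_id
    best = min(rows, key=lambda r: (-r[1], r[0]))
    return best[0]


# ---------------------------------------------------------------------------
# Selection flow
# ---------------------------------------------------------------------------

def select_cohort(records: Sequence[PatientRecord], window: StudyWindow,
                  concordance: Concordance) -> tuple[Cohort, SelectionFlow]:
    """Apply the selection flow and return the retained cohort plus counts.

    Retains patients who are (a) 18 or older at the end of the window,
    (b) linkable to an in-scope area, and (c) attended at least once inside
    the window.  Each excluded patient is counted at the first stage that
    removes them, in the order age -> address -> encounter.  Retained
    patients get their ``area_id`` filled in.
    """
    flow = SelectionFlow(input_total=len(records))
    kept: list[PatientRecord] = []
    for rec in records:
        # the adult rule is calendar age: the 18th birthday on the window end
        # itself is not "under 18"
        if rec.calendar_age_at(window.end) < ADULT_AGE_YEARS:
            flow.excluded_under_18 += 1
            continue
        area_id = link_area(rec, concordance)
        if area_id is UNRESOLVED:
            flow.excluded_no_valid_address += 1
            continue
        if not any(window.contains(d) for d in rec.attendance_dates):
            flow.excluded_no_encounter_in_window += 1
            continue
        kept.append(replace(rec, area_id=area_id))
    flow.included = len(kept)
    flow.included_alive = sum(1 for p in kept if p.vital_status == VitalStatus.ALIVE)
    flow.check()
    return Cohort(kept), flow


def time_since_last_attendance(patient: PatientRecord, window: StudyWindow) -> float:
    """Years between the most recent attendance and the follow-up reference.

    The reference is the date of death for deceased patients, else the end
    of the study window.  Attendances after the reference clamp to 0.0 with
    a warning.  Requires at least one attendance.
    """
    if not patient.attendance_dates:
        raise ValidationError(f"patient {patient.patient_id!r} has no attendance dates")
    reference = patient.date_of_death if patient.vital_status == VitalStatus.DECEASED \
        else window.end
    gap_days = (reference - max(patient.attendance_dates)).days
    if gap_days < 0:
        logger.warning("patient %s attended after the follow-up reference date; gap clamped to 0",
                       patient.patient_id)
        return 0.0
    return gap_days / DAYS_PER_YEAR


def flag_lost_to_follow_up(patient: PatientRecord, window: StudyWindow) -> bool:
    """True iff the care gap is strictly longer than three years."""
    return time_since_last_attendance(patient, window) > LTF_THRESHOLD_YEARS


def map_diagnoses(patient: PatientRecord,
                  mapping_table: Mapping[str, str]) -> list[str]:
    """Replace source diagnosis codes by standardised labels.

    Unmapped codes become ``"Unmapped"`` (logged); labels are deduplicated
    per patient, preserving first-seen order.
    """
    labels: list[str] = []
    for code in patient.diagnoses:
        label = mapping_table.get(code)
        if label is None:
            logger.warning("patient %s: diagnosis code %r not in mapping table",
                           patient.patient_id, code)
            label = "Unmapped"
        if label not in labels:
            labels.append(label)
    return labels


def read_diagnosis_map(path: Union[str, Path]) -> dict[str, str]:
    """Load the (source_code, standard_label) mapping CSV."""
    table: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            table[row["source_code"].strip()] = row["standard_label"].strip()
    return table


# ---------------------------------------------------------------------------
# Global filters
# ---------------------------------------------------------------------------

@dataclass
class GlobalFilters:
    """Interactive cohort filters; empty/None means no restriction."""

    age_min: Optional[float] = None
    age_max: Optional[float] = None
    sexes: frozenset[Sex] = frozenset()
    vital_statuses: frozenset[VitalStatus] = frozenset()
    severities: frozenset[Severity] = frozenset()
    attendance_window: Optional[tuple[date, date]] = None
    max_years_since_last: Optional[float] = None

    def __post_init__(self) -> None:
        if (self.age_min is not None and self.age_max is not None
                and self.age_min > self.age_max):
            raise ValidationError("age filter: min > max")
        if self.age_min is not None and self.age_min < 0:
            raise ValidationError("age filter: negative minimum")
        if self.attendance_window is not None:
            lo, hi = self.attendance_window
            if lo > hi:
                raise ValidationError("attendance-period filter: start > end")


def apply_global_filters(cohort: Cohort, filters: GlobalFilters,
                         window: StudyWindow) -> Cohort:
    """Intersection of all active filter criteria (age at window end)."""
    kept = []
    for p in cohort:
        age = p.age_at(window.end)
        if filters.age_min is not None and age < filters.age_min:
            continue
        if filters.age_max is not None and age > filters.age_max:
            continue
        if filters.sexes and p.sex not in filters.sexes:
            continue
        if filters.vital_statuses and p.vital_status not in filters.vital_statuses:
            continue
        if filters.severities and p.severity not in filters.severities:
            continue
        if filters.attendance_window is not None:
            lo, hi = filters.attendance_window
            if not any(lo <= d <= hi for d in p.attendance_dates):
                continue
        if filters.max_years_since_last is not None:
            if time_since_last_attendance(p, window) > filters.max_years_since_last:
                continue
        kept.append(p)
    return Cohort(kept)


# ---------------------------------------------------------------------------
# Aggregation to areas
# ---------------------------------------------------------------------------

@dataclass
class AreaAggregate:
    """Per-area patient counts; count fields become Masked in public mode."""

    area_id: str
    n_patients: object = 0
    n_by_severity: dict = field(default_factory=dict)
    n_lost_to_follow_up: object = 0
    diagnosis_counts: dict = field(default_factory=dict)
    masked: bool = False


def aggregate_to_areas(cohort: Cohort, areas: AreaSet, window: StudyWindow,
                       diagnosis_map: Optional[Mapping[str, str]] = None,
                       ) -> list[AreaAggregate]:
    """Tally patients into areas: one aggregate per area, zeros included.

    Every cohort patient must carry a resolved ``area_id`` present in
    ``areas``.  Diagnosis tallies use standardised labels when a mapping
    table is supplied, raw codes otherwise.
    """
    by_area: dict[str, AreaAggregate] = {
        a.area_id: AreaAggregate(area_id=a.area_id,
                                 n_by_severity={s: 0 for s in Severity})
        for a in areas
    }
    for p in cohort:
        if p.area_id is None or p.area_id not in by_area:
            raise ValidationError(
                f"patient {p.patient_id!r} has area_id {p.area_id!r} not in the area set")
        agg = by_area[p.area_id]
        agg.n_patients += 1
        agg.n_by_severity[p.severity] += 1
        if flag_lost_to_follow_up(p, window):
            agg.n_lost_to_follow_up += 1
        labels = map_diagnoses(p, diagnosis_map) if diagnosis_map is not None \
            else list(dict.fromkeys(p.diagnoses))
        for label in labels:
            agg.diagnosis_counts[label] = agg.diagnosis_counts.get(label, 0) + 1
    return list(by_area.values())


# ---------------------------------------------------------------------------
# Demographic summary (overall and per severity stratum)
# ---------------------------------------------------------------------------

@dataclass
class StratumSummary:
    n: int
    age_mean: Optional[float]
    age_sd: Optional[float]
    n_female: int
    pct_female: Optional[float]
    attendances_mean: Optional[float]
    attendances_sd: Optional[float]
    years_since_last_mean: Optional[float]
    years_since_last_sd: Optional[float]
    pct_lost_to_follow_up: Optional[float]
    diagnosis_counts: dict[str, int]
    diagnosis_pcts: dict[str, float]


@dataclass
class CohortSummary:
    """Demographic and diagnosis summary, overall and by disease severity."""

    overall: StratumSummary
    by_severity: dict[Severity, StratumSummary]


def _mean_sd(values: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    # sample SD (n-1); undefined moments reported as None, never NaN
    if not values:
        return None, None
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None
    return mean, sd


def _summarize_stratum(patients: Sequence[PatientRecord], window: StudyWindow,
                       diagnosis_map: Optional[Mapping[str, str]]) -> StratumSummary:
    n = len(patients)
    ages = [p.age_at(window.end) for p in patients]
    attendances = [len(p.attendance_dates) for p in patients]
    gaps = [time_since_last_attendance(p, window) for p in patients]
    age_mean, age_sd = _mean_sd(ages)
    att_mean, att_sd = _mean_sd([float(a) for a in attendances])
    gap_mean, gap_sd = _mean_sd(gaps)
    n_female = sum(1 for p in patients if p.sex == Sex.FEMALE)
    n_ltf = sum(1 for p in patients if flag_lost_to_follow_up(p, window))
    diag_counts: dict[str, int] = {}
    for p in patients:
        labels = map_diagnoses(p, diagnosis_map) if diagnosis_map is not None \
            else list(dict.fromkeys(p.diagnoses))
        for label in labels:
            diag_counts[label] = diag_counts.get(label, 0) + 1
    diag_counts = dict(sorted(diag_counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return StratumSummary(
        n=n,
        age_mean=age_mean, age_sd=age_sd,
        n_female=n_female,
        pct_female=100.0 * n_female / n if n else None,
        attendances_mean=att_mean, attendances_sd=att_sd,
        years_since_last_mean=gap_mean, years_since_last_sd=gap_sd,
        pct_lost_to_follow_up=100.0 * n_ltf / n if n else None,
        diagnosis_counts=diag_counts,
        diagnosis_pcts={k: 100.0 * v / n for k, v in diag_counts.items()} if n else {},
    )


def summarize_cohort(cohort: Cohort, window: StudyWindow,
                     diagnosis_map: Optional[Mapping[str, str]] = None) -> CohortSummary:
    """Build the demographic/diagnosis summary table, overall and by severity."""
    overall = _summarize_stratum(cohort.patients, window, diagnosis_map)
    by_sev = {
        s: _summarize_stratum([p for p in cohort if p.severity == s], window, diagnosis_map)
        for s in Severity
    }
    return CohortSummary(overall=overall, by_severity=by_sev)


# ---------------------------------------------------------------------------
# Patient CSV I/O
# ---------------------------------------------------------------------------

PATIENT_CSV_COLUMNS = [
    "patient_id", "date_of_birth", "sex", "vital_status", "date_of_death",
    "postcode", "suburb", "state", "severity", "diagnosis_codes", "attendance_dates",
]


def read_patients(path: Union[str, Path]) -> list[PatientRecord]:
    """Load patient records from CSV (ISO dates; ';'-delimited list fields)."""
    records: list[PatientRecord] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            dod = row.get("date_of_death", "").strip()
            records.append(PatientRecord(
                patient_id=row["patient_id"],
                date_of_birth=date.fromisoformat(row["date_of_birth"]),
                sex=Sex(row.get("sex") or "other/unknown"),
                vital_status=VitalStatus(row.get("vital_status") or "alive"),
                date_of_death=date.fromisoformat(dod) if dod else None,
                postcode=row.get("postcode") or None,
                suburb=row.get("suburb") or None,
                state=row.get("state") or None,
                severity=Severity(row.get("severity") or "Unknown"),
                diagnoses=[c for c in (row.get("diagnosis_codes") or "").split(";") if c],
                attendance_dates=[date.fromisoformat(d)
                                  for d in (row.get("attendance_dates") or "").split(";") if d],
            ))
    return records


def write_patients(records: Sequence[PatientRecord], path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PATIENT_CSV_COLUMNS)
        for p in records:
            writer.writerow([
                p.patient_id,
                p.date_of_birth.isoformat(),
                p.sex.value,
                p.vital_status.value,
                p.date_of_death.isoformat() if p.date_of_death else "",
                p.postcode or "",
                p.suburb or "",
                p.state or "",
                p.severity.value,
                ";".join(p.diagnoses),
                ";".join(d.isoformat() for d in p.attendance_dates),
            ])
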