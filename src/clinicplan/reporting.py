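"""Tool state, input loading, area-focus summaries and the five-section report.

The interactive front end is deliberately out of scope; everything it would
display — choropleth layers, clinic tables, accessibility summaries, area
focus panels — is reproduced here as a pure function of a serializable
:class:`ToolState` plus the loaded inputs, so any front end can be layered
on top.  The downloadable report has exactly five content sections in fixed
order: Patient Data, Area Data, Current ACHD Clinics, New ACHD Clinics and
Area Focus, preceded by a provenance block (config hash, seed, timestamp).
Re-running with the same state and inputs yields an identical body.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from . import accessibility as acc
from .accessibility import ALL_SCOPES, CandidateComparison, ClinicTableRow
from .cohort import (AreaAggregate, Concordance, GlobalFilters,
                     PatientRecord, SelectionFlow, Severity, Sex, StudyWindow,
                     VitalStatus, aggregate_to_areas, apply_global_filters,
                     read_diagnosis_map, read_patients, select_cohort,
                     summarize_cohort)
from .geo_model import (AreaSet, ClinicSet, Facility, FacilityRole,
                        TravelTimeMatrix, ValidationError, read_areas,
                        read_facilities, read_travel_matrix)
from .privacy import MaskPolicy, MaskMode, Masked, mask_aggregates, \
    mask_clinic_rows, serialize_count

logger = logging.getLogger(__name__)

SECTION_ORDER = ["Patient Data", "Area Data", "Current ACHD Clinics",
                 "New ACHD Clinics", "Area Focus"]


# ---------------------------------------------------------------------------
# Inputs
# ---------------------------------------------------------------------------

@dataclass
class PlanningInputs:
    """The loaded input bundle the whole pipeline consumes."""

    areas: AreaSet
    facilities: dict[str, Facility]
    ttm: TravelTimeMatrix
    records: list[PatientRecord]
    concordance: Concordance
    diagnosis_map: Optional[dict[str, str]]
    window: StudyWindow

    def current_clinic_set(self) -> ClinicSet:
        return ClinicSet([fid for fid, f in sorted(self.facilities.items())
                          if f.role == FacilityRole.CURRENT_CLINIC])


def load_inputs(directory: Union[str, Path],
                window: Optional[StudyWindow] = None) -> PlanningInputs:
    """Load a bundle directory written by the generator (or hand-assembled).

    Expects areas.geojson, areas.csv, facilities.csv, travel_times.csv,
    patients.csv, concordance.csv and optionally diagnosis_map.csv and
    config.yaml (from which the study window is taken unless given).
    """
    d = Path(directory)
    if window is None:
        cfg_path = d / "config.yaml"
        if cfg_path.exists():
            with open(cfg_path) as fh:
                cfg = yaml.safe_load(fh) or {}
            window = StudyWindow(date.fromisoformat(str(cfg["window_start"])),
                                 date.fromisoformat(str(cfg["window_end"])))
        else:
            raise ValidationError("no study window given and no config.yaml in bundle")
    diag_path = d / "diagnosis_map.csv"
    return PlanningInputs(
        areas=read_areas(d / "areas.geojson", d / "areas.csv"),
        facilities=read_facilities(d / "facilities.csv"),
        ttm=read_travel_matrix(d / "travel_times.csv"),
        records=read_patients(d / "patients.csv"),
        concordance=Concordance.read_csv(d / "concordance.csv"),
        diagnosis_map=read_diagnosis_map(diag_path) if diag_path.exists() else None,
        window=window,
    )


def inputs_from_bundle(bundle) -> PlanningInputs:
    """Adapt an in-memory synthetic bundle (no disk round trip)."""
    return PlanningInputs(areas=bundle.areas, facilities=bundle.facilities,
                          ttm=bundle.ttm, records=bundle.records,
                          concordance=bundle.concordance,
                          diagnosis_map=bundle.diagnosis_map,
                          window=bundle.window)


# ---------------------------------------------------------------------------
# Tool state
# ---------------------------------------------------------------------------

@dataclass
class ToolState:
    """Everything the interactive tool would hold; fully serializable."""

    filters: GlobalFilters = field(default_factory=GlobalFilters)
    scope: str = "All"
    layer: str = "achd_population"  # or "drive_time"
    current_clinics: Optional[list[str]] = None  # None = all role current_clinic
    candidate_clinics: list[str] = field(default_factory=list)
    focus_areas: list[str] = field(default_factory=list)
    mask_mode: MaskMode = MaskMode.PRIVATE
    mask_threshold: int = 5
    threshold_hours: float = acc.DEFAULT_THRESHOLD_HOURS
    seed: Optional[int] = None

    @property
    def policy(self) -> MaskPolicy:
        return MaskPolicy(threshold=self.mask_threshold, mode=self.mask_mode)

    def to_dict(self) -> dict:
        f = self.filters
        return {
            "filters": {
                "age_min": f.age_min, "age_max": f.age_max,
                "sexes": sorted(s.value for s in f.sexes),
                "vital_statuses": sorted(v.value for v in f.vital_statuses),
                "severities": sorted(s.value for s in f.severities),
                "attendance_window": [d.isoformat() for d in f.attendance_window]
                if f.attendance_window else None,
                "max_years_since_last": f.max_years_since_last,
            },
            "scope": self.scope, "layer": self.layer,
            "current_clinics": self.current_clinics,
            "candidate_clinics": list(self.candidate_clinics),
            "focus_areas": list(self.focus_areas),
            "mask_mode": self.mask_mode.value,
            "mask_threshold": self.mask_threshold,
            "threshold_hours": self.threshold_hours,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToolState":
        fd = d.get("filters") or {}
        aw = fd.get("attendance_window")
        filters = GlobalFilters(
            age_min=fd.get("age_min"), age_max=fd.get("age_max"),
            sexes=frozenset(Sex(s) for s in fd.get("sexes") or []),
            vital_statuses=frozenset(VitalStatus(v) for v in fd.get("vital_statuses") or []),
            severities=frozenset(Severity(s) for s in fd.get("severities") or []),
            attendance_window=(date.fromisoformat(aw[0]), date.fromisoformat(aw[1]))
            if aw else None,
            max_years_since_last=fd.get("max_years_since_last"),
        )
        return cls(
            filters=filters,
            scope=d.get("scope", "All"),
            layer=d.get("layer", "achd_population"),
            current_clinics=d.get("current_clinics"),
            candidate_clinics=list(d.get("candidate_clinics") or []),
            focus_areas=list(d.get("focus_areas") or []),
            mask_mode=MaskMode(d.get("mask_mode", "private")),
            mask_threshold=int(d.get("mask_threshold", 5)),
            threshold_hours=float(d.get("threshold_hours", 1.0)),
            seed=d.get("seed"),
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "ToolState":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Area focus
# ---------------------------------------------------------------------------

def area_focus(area_ids: Sequence[str], aggregates: Sequence[AreaAggregate],
               areas: AreaSet, policy: MaskPolicy) -> list[dict]:
    """Per-area detail panels, accumulated in selection order.

    Patient and diagnosis counts are masked as the policy requires; area
    attributes (IRSD decile, remoteness, Indigenous percentage, population)
    describe the area, not patients, and are always shown.
    """
    agg_by_id = {a.area_id: a for a in mask_aggregates(aggregates, policy)}
    out = []
    for aid in area_ids:
        if aid not in areas:
            raise ValidationError(f"area focus requested for unknown area {aid!r}")
        area = areas[aid]
        agg = agg_by_id.get(aid, AreaAggregate(area_id=aid))
        out.append({
            "area_id": aid,
            "name": area.name,
            "n_patients": serialize_count(agg.n_patients),
            "n_lost_to_follow_up": serialize_count(agg.n_lost_to_follow_up),
            "diagnosis_counts": {k: serialize_count(v)
                                 for k, v in agg.diagnosis_counts.items()},
            "irsd_decile": area.irsd_decile,
            "remoteness": area.remoteness.value if area.remoteness else None,
            "indigenous_pct": area.indigenous_pct,
            "population": area.population,
        })
    return out


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

@dataclass
class Report:
    """Structured report data plus its rendered Markdown body."""

    state: ToolState
    flow: SelectionFlow
    summary_table: dict            # Patient Data (count cells pre-masked)
    layer_values: dict             # Area Data: active choropleth layer
    scope_summaries: dict          # Area Data: per-scope accessibility
    current_rows: list[ClinicTableRow]
    new_rows: list[ClinicTableRow]
    comparison: Optional[CandidateComparison]
    focus: list[dict]
    provenance: dict
    body: str = ""

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.body)

    def count_cells(self) -> list:
        """Every patient-count cell the report displays (for privacy audit)."""
        cells: list = [self.flow.input_total, self.flow.included,
                       self.flow.included_alive, self.flow.excluded_under_18,
                       self.flow.excluded_no_valid_address,
                       self.flow.excluded_no_encounter_in_window]
        for stratum in self.summary_table.values():
            cells.append(stratum["n"])
            cells.append(stratum["n_female"])
            cells.extend(stratum["diagnosis_counts"].values())
        if self.state.layer == "achd_population":
            cells.extend(v for v in self.layer_values.values() if v is not None)
        for row in self.current_rows + self.new_rows:
            cells.extend([row.n_patients_within_threshold, row.n_ltf_within_threshold])
        for panel in self.focus:
            cells.append(panel["n_patients"])
            cells.append(panel["n_lost_to_follow_up"])
            cells.extend(panel["diagnosis_counts"].values())
        return cells


def _fmt(x, nd=2) -> str:
    if x is None:
        return "-"
    if isinstance(x, Masked) or x == "masked":
        return "masked"
    if isinstance(x, float):
        return f"{x:.{nd}f}"
    return str(x)


def _mask_stat_count(c, policy: MaskPolicy):
    if policy.active and isinstance(c, int) and 0 < c < policy.threshold:
        from .privacy import MASKED
        return MASKED
    return c


def _summary_to_table(summary, policy: MaskPolicy) -> dict:
    table = {}
    strata = [("All", summary.overall)] + [
        (s.value, summary.by_severity[s]) for s in Severity]
    for name, st in strata:
        table[name] = {
            "n": _mask_stat_count(st.n, policy),
            "age_mean": st.age_mean, "age_sd": st.age_sd,
            "n_female": _mask_stat_count(st.n_female, policy),
            "pct_female": st.pct_female,
            "attendances_mean": st.attendances_mean, "attendances_sd": st.attendances_sd,
            "years_since_last_mean": st.years_since_last_mean,
            "years_since_last_sd": st.years_since_last_sd,
            "pct_lost_to_follow_up": st.pct_lost_to_follow_up,
            "diagnosis_counts": {k: _mask_stat_count(v, policy)
                                 for k, v in st.diagnosis_counts.items()},
        }
    return table


def _flow_counts_masked(flow: SelectionFlow, policy: MaskPolicy) -> SelectionFlow:
    if not policy.active:
        return flow
    masked = SelectionFlow()
    for f in ("input_total", "excluded_under_18", "excluded_no_valid_address",
              "excluded_no_encounter_in_window", "included", "included_alive"):
        setattr(masked, f, _mask_stat_count(getattr(flow, f), policy))
    return masked


def build_report(state: ToolState, inputs: PlanningInputs,
                 timestamp: Optional[str] = None) -> Report:
    """Recompute every table from the state and render the report.

    Pure: identical (state, inputs) give byte-identical bodies; only the
    provenance timestamp varies (pass ``timestamp`` to pin it).
    """
    policy = state.policy
    current = ClinicSet(state.current_clinics) if state.current_clinics is not None \
        else inputs.current_clinic_set()
    current.validate_against(inputs.facilities)
    candidates = ClinicSet(list(state.candidate_clinics))
    candidates.validate_against(inputs.facilities)
    overlap = [f for f in candidates if f in current]
    if overlap:
        raise ValidationError(f"candidate clinics already open: {overlap}")

    cohort_all, flow = select_cohort(inputs.records, inputs.window, inputs.concordance)
    cohort = apply_global_filters(cohort_all, state.filters, inputs.window)
    aggregates = aggregate_to_areas(cohort, inputs.areas, inputs.window,
                                    inputs.diagnosis_map)
    summary = summarize_cohort(cohort, inputs.window, inputs.diagnosis_map) \
        if len(cohort) else None

    combined = current.union(candidates) if len(candidates) else current
    if state.layer == "drive_time":
        layer_values = acc.drive_time_layer(combined, inputs.ttm, inputs.areas)
    else:
        masked_aggs = mask_aggregates(aggregates, policy)
        layer_values = {a.area_id: a.n_patients for a in masked_aggs}

    scope_summaries = {s: acc.accessibility_summary(
        aggregates, combined, inputs.ttm, state.threshold_hours, s, inputs.areas)
        for s in ALL_SCOPES}
    current_rows = mask_clinic_rows(
        [acc.clinic_reach(fid, aggregates, inputs.ttm, state.threshold_hours)
         for fid in current], policy)
    new_rows = mask_clinic_rows(
        [acc.clinic_reach(fid, aggregates, inputs.ttm, state.threshold_hours)
         for fid in candidates], policy)
    comparison = acc.evaluate_candidates(current, candidates, aggregates,
                                         inputs.ttm, state.threshold_hours,
                                         inputs.areas) if len(candidates) else None
    focus = area_focus(state.focus_areas, aggregates, inputs.areas, policy)

    report = Report(
        state=state,
        flow=_flow_counts_masked(flow, policy),
        summary_table=_summary_to_table(summary, policy) if summary else {},
        layer_values=layer_values,
        scope_summaries=scope_summaries,
        current_rows=current_rows,
        new_rows=new_rows,
        comparison=comparison,
        focus=focus,
        provenance={
            "config_hash": state.config_hash(),
            "seed": state.seed,
            "mode": state.mask_mode.value,
            "threshold_hours": state.threshold_hours,
        },
    )
    report.body = _render(report)
    if timestamp is None:
        timestamp = datetime.now().isoformat(timespec="seconds")
    report.provenance["timestamp"] = timestamp
    return report


def _render(r: Report) -> str:
    lines: list[str] = []
    add = lines.append
    add("# Clinic Planning Report")
    add("")
    add(f"- config hash: `{r.provenance['config_hash']}`")
    add(f"- seed: {r.provenance['seed']}")
    add(f"- mode: {r.provenance['mode']}")
    add(f"- coverage threshold: {r.provenance['threshold_hours']} h")
    add("")

    add("## Patient Data")
    add("")
    f = r.flow
    add("| Selection stage | Patients |")
    add("|---|---|")
    add(f"| Database extract | {_fmt(f.input_total)} |")
    add(f"| Excluded: under 18 at study end | {_fmt(f.excluded_under_18)} |")
    add(f"| Excluded: no valid address | {_fmt(f.excluded_no_valid_address)} |")
    add(f"| Excluded: no attendance in window | {_fmt(f.excluded_no_encounter_in_window)} |")
    add(f"| Included | {_fmt(f.included)} |")
    add(f"| Included and alive | {_fmt(f.included_alive)} |")
    add("")
    if r.summary_table:
        strata = list(r.summary_table)
        add("| | " + " | ".join(strata) + " |")
        add("|---|" + "---|" * len(strata))
        rows = [
            ("N", "n", 0), ("Age mean", "age_mean", 2), ("Age SD", "age_sd", 2),
            ("Female N", "n_female", 0), ("Female %", "pct_female", 2),
            ("Attendances mean", "attendances_mean", 2),
            ("Attendances SD", "attendances_sd", 2),
            ("Years since last visit mean", "years_since_last_mean", 2),
            ("Years since last visit SD", "years_since_last_sd", 2),
            ("Lost to follow up %", "pct_lost_to_follow_up", 2),
        ]
        for label, key, nd in rows:
            add(f"| {label} | " + " | ".join(
                _fmt(r.summary_table[s][key], nd) for s in strata) + " |")
        add("")

    add("## Area Data")
    add("")
    add(f"Active layer: {r.state.layer}; scope: {r.state.scope}")
    add("")
    add("| Scope | Patients | Covered | Uncovered | Within threshold | % within | Mean h | Max h |")
    add("|---|---|---|---|---|---|---|---|")
    for scope, s in r.scope_summaries.items():
        add(f"| {scope} | {s.n_patients_in_scope} | {s.n_patients_covered} | "
            f"{s.n_patients_uncovered} | {s.n_within_threshold} | "
            f"{_fmt(s.pct_within_threshold)} | {_fmt(s.mean_time)} | {_fmt(s.max_time)} |")
    add("")

    def clinic_table(rows: Sequence[ClinicTableRow]) -> None:
        add("| Clinic | Patients | ltf |")
        add("|---|---|---|")
        for row in rows:
            add(f"| {row.facility_id} | {_fmt(row.n_patients_within_threshold)} | "
                f"{_fmt(row.n_ltf_within_threshold)} |")
        add("")

    add("## Current ACHD Clinics")
    add("")
    clinic_table(r.current_rows)

    add("## New ACHD Clinics")
    add("")
    if r.new_rows:
        clinic_table(r.new_rows)
        if r.comparison is not None:
            add("| Scope | % within before | % within after | Mean h before | "
                "Mean h after | Max h before | Max h after | Patients gained |")
            add("|---|---|---|---|---|---|---|---|")
            for scope in r.comparison.before:
                b, a = r.comparison.before[scope], r.comparison.after[scope]
                add(f"| {scope} | {_fmt(b.pct_within_threshold)} | "
                    f"{_fmt(a.pct_within_threshold)} | {_fmt(b.mean_time)} | "
                    f"{_fmt(a.mean_time)} | {_fmt(b.max_time)} | {_fmt(a.max_time)} | "
                    f"{r.comparison.delta_patients_within[scope]} |")
            add("")
    else:
        add("No candidate clinics selected.")
        add("")

    add("## Area Focus")
    add("")
    if r.focus:
        for panel in r.focus:
            add(f"### {panel['name']} ({panel['area_id']})")
            add("")
            add(f"- patients: {_fmt(panel['n_patients'])}")
            add(f"- lost to follow up: {_fmt(panel['n_lost_to_follow_up'])}")
            diag = ", ".join(f"{k}: {_fmt(v)}" for k, v in panel["diagnosis_counts"].items())
            add(f"- diagnoses: {diag if diag else 'none'}")
            add(f"- IRSD decile: {_fmt(panel['irsd_decile'])}")
            add(f"- remoteness: {panel['remoteness']}")
            add(f"- Indigenous %: {_fmt(panel['indigenous_pct'])}")
            add(f"- population: {panel['population']}")
            add("")
    else:
        add("No areas selected.")
        add("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Table serialization
# ---------------------------------------------------------------------------

def clinic_rows_to_records(rows: Sequence[ClinicTableRow]) -> list[dict]:
    return [{"facility_id": r.facility_id,
             "patients": serialize_count(r.n_patients_within_threshold),
             "ltf": serialize_count(r.n_ltf_within_threshold)} for r in rows]


def write_clinic_table(rows: Sequence[ClinicTableRow], path: Union[str, Path]) -> None:
    """CSV (or JSON, by extension) export of a clinic reach table."""
    recs = clinic_rows_to_records(rows)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(recs, indent=1))
        return
    import csv as _csv
    with open(path, "w", newline="") as fh:
        w = _csv.DictWriter(fh, fieldnames=["facility_id", "patients", "ltf"])
        w.writeheader()
        w.writerows(recs)
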