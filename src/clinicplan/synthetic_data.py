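"""Seeded synthetic inputs: areas, facilities, travel times and a patient cohort.

The generator emulates the structure of the real inputs — census-style area
polygons with sociodemographic attributes, an area-to-hospital driving-time
matrix, and a specialist-clinic patient database — without any download or
private data.  Geometry is a deliberate grid-world: a rectangular grid of
square cells with a designated "city" corner; regions and remoteness classes
are assigned by distance rank from that corner, clinics sit near the corner,
and driving time grows linearly with centroid distance plus noise.  The
accessibility engine consumes only the matrix, so geometric realism is
unnecessary and the grid keeps oracle checks trivial.

Cohort marginals default to the published study population: mean age 43.70
(SD 16.65, adults only), 49.21% female, severity mix 1230/894/456/476 over
Simple/Moderate/Complex/Unknown (N = 3056), per-severity clinic-attendance
means 2.29/4.27/5.86/1.9, and per-severity lost-to-follow-up fractions
68.13/34.00/21.71/4.62%.  Because truncating an age distribution at 18
shifts its mean, the pre-truncation location is calibrated numerically so
the *realised* mean matches the target.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from scipy import optimize, stats
from shapely.geometry import Polygon

from .cohort import (Concordance, PatientRecord, Severity, Sex, StudyWindow,
                     VitalStatus, write_patients)
from .geo_model import (Area, AreaSet, Facility, FacilityRole, Region,
                        Remoteness, TravelTimeMatrix, ValidationError)

logger = logging.getLogger(__name__)

REMOTENESS_ORDER = [Remoteness.MAJOR_CITIES, Remoteness.INNER_REGIONAL,
                    Remoteness.OUTER_REGIONAL, Remoteness.REMOTE,
                    Remoteness.VERY_REMOTE]
REGION_ORDER = [Region.GREATER_SYDNEY, Region.ACT, Region.REST_OF_STATE]

# severity mix from the published cohort: 1230/894/456/476 of 3056
_SEV_COUNTS = np.array([1230.0, 894.0, 456.0, 476.0])
SEVERITY_ORDER = [Severity.SIMPLE, Severity.MODERATE, Severity.COMPLEX, Severity.UNKNOWN]


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic world; the seed fully determines output."""

    seed: int = 0
    # --- geography ---
    n_areas: int = 192
    grid_cols: int = 16
    cell_deg: float = 0.25
    origin_lon: float = 144.0
    origin_lat: float = -38.0
    region_mix: tuple[float, float, float] = (0.35, 0.05, 0.60)
    remoteness_mix: tuple[float, float, float, float, float] = (
        0.7445, 0.1902, 0.0603, 0.0042, 0.0008)
    mean_population: float = 10000.0
    sd_population: float = 2000.0
    # --- facilities & travel ---
    n_facilities: int = 40
    n_current_clinics: int = 4
    speed_kmh: float = 80.0
    winding_factor: float = 1.3
    noise_scale_hours: float = 0.05
    uncovered_remote_fraction: float = 0.10
    # --- cohort ---
    cohort_size: int = 3056
    window_start: date = date(2000, 1, 1)
    window_end: date = date(2022, 7, 1)
    age_mean: float = 43.70
    age_sd: float = 16.65
    min_adult_age: float = 18.0
    female_fraction: float = 0.4921
    severity_fractions: tuple[float, float, float, float] = tuple(
        float(x) for x in _SEV_COUNTS / _SEV_COUNTS.sum())
    attendance_means: tuple[float, float, float, float] = (2.29, 4.27, 5.86, 1.9)
    ltf_fractions: tuple[float, float, float, float] = (0.6813, 0.3400, 0.2171, 0.0462)
    deceased_fraction: float = 0.123
    rural_thinning: float = 0.8
    severity_remoteness_interaction: float = 0.0
    # --- contamination (exercises the selection flow) ---
    minor_rate: float = 0.02
    invalid_address_rate: float = 0.015
    out_of_window_rate: float = 0.01

    def __post_init__(self) -> None:
        for name in ("region_mix", "remoteness_mix", "severity_fractions"):
            vec = getattr(self, name)
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ValidationError(f"{name} must sum to 1, got {sum(vec)}")

    @property
    def window(self) -> StudyWindow:
        return StudyWindow(self.window_start, self.window_end)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_start"] = self.window_start.isoformat()
        d["window_end"] = self.window_end.isoformat()
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for k in ("window_start", "window_end"):
            if k in d and isinstance(d[k], str):
                d[k] = date.fromisoformat(d[k])
        for k in ("region_mix", "remoteness_mix", "severity_fractions",
                  "attendance_means", "ltf_fractions"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _allocate(n: int, fractions: Sequence[float], labels: Sequence) -> list:
    """Largest-remainder allocation of n items over classes.

    A non-empty class whose share rounds to zero is dropped with a warning.
    """
    raw = np.asarray(fractions, dtype=float) * n
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    out = []
    for label, c, f in zip(labels, counts, fractions):
        if f > 0 and c == 0:
            logger.warning("class %s has fraction %.4f but rounds to 0 of %d; dropped",
                           label, f, n)
        out.extend([label] * c)
    return out


# ---------------------------------------------------------------------------
# Areas
# ---------------------------------------------------------------------------

_INDIGENOUS_BASE = {Remoteness.MAJOR_CITIES: 1.5, Remoteness.INNER_REGIONAL: 4.0,
                    Remoteness.OUTER_REGIONAL: 8.0, Remoteness.REMOTE: 15.0,
                    Remoteness.VERY_REMOTE: 30.0}


def generate_areas(config: GeneratorConfig) -> tuple[AreaSet, dict]:
    """Build the grid-world AreaSet plus its GeoJSON document.

    Square cells on a ``grid_cols``-wide grid; regions are contiguous
    distance-rank blocks from the city corner per the region mix; remoteness
    classes likewise per the remoteness mix; IRSD decile uniform 1-10;
    Aboriginal and Torres Strait Islander percentage drawn higher in remoter
    classes; population ~ N(mean, sd) clipped at 500.
    """
    if config.n_areas < 1:
        raise ValidationError("n_areas must be >= 1")
    rng = np.random.default_rng([config.seed % (2**31), 101])
    cell = config.cell_deg
    cells = []
    for i in range(config.n_areas):
        row, col = divmod(i, config.grid_cols)
        lon = config.origin_lon + col * cell
        lat = config.origin_lat + row * cell
        cells.append((i, lon, lat))
    # distance of each centroid from the city corner (grid origin)
    dist = {i: math.hypot(lon + cell / 2 - config.origin_lon,
                          lat + cell / 2 - config.origin_lat)
            for i, lon, lat in cells}
    rank_order = sorted(dist, key=lambda i: (dist[i], i))
    remoteness_by_rank = _allocate(config.n_areas, config.remoteness_mix, REMOTENESS_ORDER)
    remoteness = {i: remoteness_by_rank[r] for r, i in enumerate(rank_order)}
    # regions: the capital-territory block is a compact disc of cells around an
    # anchor at ~55% of the grid diagonal; the metro region is the block nearest
    # the city corner among the rest; everything else is rest-of-state
    region_sizes = [len([x for x in _allocate(config.n_areas, config.region_mix,
                                              REGION_ORDER) if x == r])
                    for r in REGION_ORDER]
    n_rows = math.ceil(config.n_areas / config.grid_cols)
    anchor = (config.origin_lon + 0.55 * config.grid_cols * cell,
              config.origin_lat + 0.55 * n_rows * cell)
    by_anchor = sorted(dist, key=lambda i: (
        math.hypot(cells[i][1] + cell / 2 - anchor[0],
                   cells[i][2] + cell / 2 - anchor[1]), i))
    act_ids = set(by_anchor[: region_sizes[1]])
    region = {i: Region.ACT for i in act_ids}
    n_gs = region_sizes[0]
    for i in rank_order:
        if i in region:
            continue
        region[i] = Region.GREATER_SYDNEY if n_gs > 0 else Region.REST_OF_STATE
        n_gs -= 1 if region[i] == Region.GREATER_SYDNEY else 0

    irsd = rng.integers(1, 11, size=config.n_areas)
    pops = np.clip(rng.normal(config.mean_population, config.sd_population,
                              size=config.n_areas), 500, None).round().astype(int)
    noise = rng.lognormal(0.0, 0.3, size=config.n_areas)

    areas, features = [], []
    for i, lon, lat in cells:
        aid = f"A{i + 1:04d}"
        poly = Polygon([(lon, lat), (lon + cell, lat), (lon + cell, lat + cell),
                        (lon, lat + cell), (lon, lat)])
        ind_pct = float(np.clip(_INDIGENOUS_BASE[remoteness[i]] * noise[i], 0.0, 100.0))
        areas.append(Area(
            area_id=aid, name=f"Area {i + 1:04d}", region=region[i],
            remoteness=remoteness[i], irsd_decile=int(irsd[i]),
            indigenous_pct=round(ind_pct, 2), population=int(pops[i]), geometry=poly,
        ))
        features.append({
            "type": "Feature",
            "properties": {"area_id": aid, "name": f"Area {i + 1:04d}"},
            "geometry": json.loads(json.dumps(poly.__geo_interface__)),
        })
    return AreaSet(areas), {"type": "FeatureCollection", "features": features}


def generate_facilities(areas: AreaSet, config: GeneratorConfig) -> dict[str, Facility]:
    """Place facilities at area centroids.

    Current clinics go to the areas closest to the city corner, with one
    clinic in the ACT block when it exists (the real service runs big-city
    clinics plus one in the capital territory).  The remaining facilities are
    candidate-eligible hospitals spread evenly across the distance ranking.
    """
    area_list = list(areas)
    corner = (config.origin_lon, config.origin_lat)
    by_dist = sorted(area_list, key=lambda a: (
        math.hypot(a.geometry.centroid.x - corner[0], a.geometry.centroid.y - corner[1]),
        a.area_id))
    n_clinics = min(config.n_current_clinics, len(by_dist))
    clinic_hosts = [a for a in by_dist[:n_clinics]]
    act_areas = [a for a in by_dist if a.region == Region.ACT]
    if act_areas and n_clinics >= 2:
        # the capital-territory clinic sits at the block's central area
        cx = sum(a.geometry.centroid.x for a in act_areas) / len(act_areas)
        cy = sum(a.geometry.centroid.y for a in act_areas) / len(act_areas)
        act_central = min(act_areas, key=lambda a: (
            math.hypot(a.geometry.centroid.x - cx, a.geometry.centroid.y - cy),
            a.area_id))
        if act_central not in clinic_hosts:
            clinic_hosts[-1] = act_central
    remaining = [a for a in by_dist if a not in clinic_hosts]
    n_hosp = min(config.n_facilities - n_clinics, len(remaining))
    if n_hosp > 0:
        idx = np.linspace(0, len(remaining) - 1, n_hosp).round().astype(int)
        hosp_hosts = [remaining[int(i)] for i in sorted(set(idx.tolist()))]
    else:
        hosp_hosts = []

    facilities: dict[str, Facility] = {}
    for k, host in enumerate(clinic_hosts):
        fid = f"C{k + 1:02d}"
        c = host.geometry.centroid
        facilities[fid] = Facility(fid, f"Clinic at {host.name}", c.x, c.y,
                                   FacilityRole.CURRENT_CLINIC)
    for k, host in enumerate(hosp_hosts):
        fid = f"H{k + 1:02d}"
        c = host.geometry.centroid
        facilities[fid] = Facility(fid, f"Hospital at {host.name}", c.x, c.y,
                                   FacilityRole.HOSPITAL)
    return facilities


# ---------------------------------------------------------------------------
# Travel matrix
# ---------------------------------------------------------------------------

KM_PER_DEGREE = 111.0


def generate_travel_matrix(areas: AreaSet, facilities: dict[str, Facility],
                           config: GeneratorConfig) -> TravelTimeMatrix:
    """Driving time = centroid distance x winding factor / speed + noise.

    Noise is multiplicative-lognormal scaled by ``noise_scale_hours`` (zero
    scale gives exactly linear times).  A configurable fraction of Remote /
    VeryRemote areas lose all entries, emulating areas with no driving-time
    data (the grey areas on the published maps).
    """
    rng = np.random.default_rng([config.seed % (2**31), 202])
    remote_ids = [a.area_id for a in areas
                  if a.remoteness in (Remoteness.REMOTE, Remoteness.VERY_REMOTE)]
    n_drop = int(round(config.uncovered_remote_fraction * len(remote_ids)))
    dropped = set(rng.choice(remote_ids, size=n_drop, replace=False)) if n_drop else set()

    entries: dict[tuple[str, str], float] = {}
    fac_items = sorted(facilities.items())
    for area in areas:
        if area.area_id in dropped:
            continue
        cx, cy = area.geometry.centroid.x, area.geometry.centroid.y
        for fid, fac in fac_items:
            km = KM_PER_DEGREE * math.hypot(cx - fac.lon, cy - fac.lat)
            base = km * config.winding_factor / config.speed_kmh
            noise = config.noise_scale_hours * float(rng.lognormal(0.0, 0.5))
            entries[(area.area_id, fid)] = base + noise
    return TravelTimeMatrix(entries)


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def calibrated_truncnorm_loc(target_mean: float, sd: float, lower: float) -> float:
    """Location of a normal whose ``lower``-truncated version has the target mean."""

    def trunc_mean(loc: float) -> float:
        a = (lower - loc) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd))

    return float(optimize.brentq(lambda m: trunc_mean(m) - target_mean,
                                 target_mean - 6 * sd, target_mean + sd))


def _days(years: float) -> timedelta:
    return timedelta(days=round(years * 365.25))


def generate_cohort(areas: AreaSet, config: GeneratorConfig,
                    ) -> tuple[list[PatientRecord], Concordance, list[tuple[str, str, str, float]]]:
    """Draw the synthetic patient list plus its postcode/suburb concordance.

    The main block of ``cohort_size`` patients all survive the selection
    flow; contamination records (minors, unmappable postcodes, attendances
    entirely before the window) are appended afterwards to exercise it.
    Per-severity attendance counts are 1 + Poisson(mean - 1), keeping the
    target mean while guaranteeing at least one visit; care gaps are a
    two-component mixture (recent ~ U[0, 3), lost ~ U(3, 15]) whose mixing
    weight is the per-severity lost-to-follow-up target.
    """
    if config.cohort_size < 1:
        raise ValidationError("cohort_size must be >= 1")
    rng = np.random.default_rng([config.seed % (2**31), 303])
    window = config.window

    area_list = list(areas)
    conc_rows = [(str(2000 + i), a.name, a.area_id, 1.0)
                 for i, a in enumerate(area_list)]
    postcode_of = {a.area_id: str(2000 + i) for i, a in enumerate(area_list)}
    concordance = Concordance(conc_rows)

    rank = {r: k for k, r in enumerate(REMOTENESS_ORDER)}
    weights = np.array([a.population * config.rural_thinning ** rank[a.remoteness]
                        for a in area_list], dtype=float)
    weights /= weights.sum()

    n = config.cohort_size
    area_idx = rng.choice(len(area_list), size=n, p=weights)
    sev_idx = rng.choice(4, size=n, p=np.asarray(config.severity_fractions))
    female = rng.random(n) < config.female_fraction
    deceased = rng.random(n) < config.deceased_fraction

    loc = calibrated_truncnorm_loc(config.age_mean, config.age_sd, config.min_adult_age)
    a_trunc = (config.min_adult_age - loc) / config.age_sd
    ages = stats.truncnorm.rvs(a_trunc, np.inf, loc=loc, scale=config.age_sd,
                               size=n, random_state=rng)

    # optional severity-remoteness interaction: shift severe classes ruralward
    if config.severity_remoteness_interaction != 0.0:
        gamma = config.severity_remoteness_interaction
        for j in range(n):
            if SEVERITY_ORDER[sev_idx[j]] in (Severity.COMPLEX, Severity.MODERATE) \
                    and rng.random() < abs(gamma):
                rural = np.array([w * (2.0 if rank[area_list[i].remoteness] > 0 else 0.5)
                                  for i, w in enumerate(weights)])
                area_idx[j] = rng.choice(len(area_list), p=rural / rural.sum())

    records: list[PatientRecord] = []
    death_lo = window.start + _days(16.0)
    death_span_days = (window.end - death_lo).days
    for j in range(n):
        sev = SEVERITY_ORDER[sev_idx[j]]
        att_mean = config.attendance_means[sev_idx[j]]
        ltf_p = config.ltf_fractions[sev_idx[j]]
        dod: Optional[date] = None
        if deceased[j]:
            dod = death_lo + timedelta(days=int(rng.integers(0, death_span_days + 1)))
        reference = dod if dod is not None else window.end
        if rng.random() < ltf_p:
            gap = float(rng.uniform(3.01, 15.0))
        else:
            gap = float(rng.uniform(0.0, 2.99))
        last_visit = reference - _days(gap)
        n_att = 1 + int(rng.poisson(max(att_mean - 1.0, 0.0)))
        earliest = max(window.start, last_visit - _days(15.0))
        visits = [last_visit]
        if n_att > 1 and last_visit > earliest:
            span = (last_visit - earliest).days
            offs = rng.integers(0, span + 1, size=n_att - 1)
            visits += [earliest + timedelta(days=int(o)) for o in offs]
        dob = window.end - _days(float(ages[j]))
        if dod is not None and dob > dod - _days(config.min_adult_age):
            dob = dod - _days(config.min_adult_age + 0.1)
        area = area_list[area_idx[j]]
        records.append(PatientRecord(
            patient_id=f"P{j + 1:05d}", date_of_birth=dob,
            sex=Sex.FEMALE if female[j] else Sex.MALE,
            vital_status=VitalStatus.DECEASED if dod else VitalStatus.ALIVE,
            date_of_death=dod, postcode=postcode_of[area.area_id],
            suburb=area.name, state="NSW",
            diagnoses=_draw_diagnoses(rng, sev),
            severity=sev, attendance_dates=sorted(visits),
        ))

    records.extend(_contamination_records(rng, config, area_list, postcode_of))
    return records, concordance, conc_rows


# in-house diagnosis codes and the share of patients carrying each;
# the mapping table (written by generate_bundle) standardises them
DIAGNOSIS_CODES = [
    ("D01", "Bicuspid Aortic Valve", 0.21),
    ("D02", "Ventricular Septal Defect", 0.20),
    ("D03", "Atrial Septal Defect", 0.18),
    ("D04", "Tetralogy of Fallot", 0.11),
    ("D05", "Patent Foramen Ovale", 0.10),
    ("D06", "Coarctation of the Aorta", 0.08),
    ("D07", "Transposition of the Great Arteries", 0.06),
    ("D08", "Other Congenital Anomaly", 0.06),
]
_DIAG_P = np.array([p for _, _, p in DIAGNOSIS_CODES])
_DIAG_P = _DIAG_P / _DIAG_P.sum()


def _draw_diagnoses(rng: np.random.Generator, severity: Severity) -> list[str]:
    k = 1 + int(rng.random() < 0.2)
    picks = rng.choice(len(DIAGNOSIS_CODES), size=k, replace=False, p=_DIAG_P)
    return [DIAGNOSIS_CODES[int(i)][0] for i in picks]


def _contamination_records(rng, config, area_list, postcode_of) -> list[PatientRecord]:
    window = config.window
    n = config.cohort_size
    n_minor = round(config.minor_rate * n)
    n_bad = round(config.invalid_address_rate * n)
    n_oow = round(config.out_of_window_rate * n)
    out: list[PatientRecord] = []
    mid = window.start + (window.end - window.start) / 2
    k = 0
    for _ in range(n_minor):
        k += 1
        age = float(rng.uniform(5.0, 17.5))
        area = area_list[int(rng.integers(0, len(area_list)))]
        out.append(PatientRecord(
            patient_id=f"X{k:04d}", date_of_birth=window.end - _days(age),
            postcode=postcode_of[area.area_id], suburb=area.name, state="NSW",
            attendance_dates=[mid]))
    for _ in range(n_bad):
        k += 1
        out.append(PatientRecord(
            patient_id=f"X{k:04d}", date_of_birth=window.end - _days(40.0),
            postcode="0000", suburb="Nowhere", state="XX",
            attendance_dates=[mid]))
    for _ in range(n_oow):
        k += 1
        area = area_list[int(rng.integers(0, len(area_list)))]
        out.append(PatientRecord(
            patient_id=f"X{k:04d}", date_of_birth=window.end - _days(40.0),
            postcode=postcode_of[area.area_id], suburb=area.name, state="NSW",
            attendance_dates=[window.start - _days(float(rng.uniform(0.1, 5.0)))]))
    return out


# ---------------------------------------------------------------------------
# Whole-bundle generation
# ---------------------------------------------------------------------------

@dataclass
class Bundle:
    """Everything the planning pipeline consumes, in memory."""

    config: GeneratorConfig
    areas: AreaSet
    geojson: dict
    facilities: dict[str, Facility]
    ttm: TravelTimeMatrix
    records: list[PatientRecord]
    concordance: Concordance
    diagnosis_map: dict[str, str]

    @property
    def window(self) -> StudyWindow:
        return self.config.window

    def current_clinic_set(self):
        from .geo_model import ClinicSet
        return ClinicSet([fid for fid, f in sorted(self.facilities.items())
                          if f.role == FacilityRole.CURRENT_CLINIC])


def generate_bundle(config: GeneratorConfig,
                    outdir: Optional[Union[str, Path]] = None) -> Bundle:
    """Generate the full synthetic input bundle; optionally write it to disk.

    When ``outdir`` is given, the bundle is written in exactly the CSV /
    GeoJSON dialects the readers consume (areas.geojson, areas.csv,
    facilities.csv, travel_times.csv, patients.csv, concordance.csv,
    diagnosis_map.csv) plus the echoed generator config (config.yaml).
    """
    areas, geojson = generate_areas(config)
    facilities = generate_facilities(areas, config)
    ttm = generate_travel_matrix(areas, facilities, config)
    records, concordance, conc_rows = generate_cohort(areas, config)
    diagnosis_map = {code: label for code, label, _ in DIAGNOSIS_CODES}
    bundle = Bundle(config=config, areas=areas, geojson=geojson,
                    facilities=facilities, ttm=ttm, records=records,
                    concordance=concordance, diagnosis_map=diagnosis_map)
    if outdir is not None:
        _write_bundle(bundle, conc_rows, Path(outdir))
    return bundle


def _write_bundle(bundle: Bundle, conc_rows, outdir: Path) -> None:
    import csv as _csv

    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "areas.geojson", "w") as fh:
        json.dump(bundle.geojson, fh, sort_keys=True, separators=(",", ":"))
    with open(outdir / "areas.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["area_id", "name", "region", "remoteness", "irsd_decile",
                    "indigenous_pct", "population"])
        for a in bundle.areas:
            w.writerow([a.area_id, a.name, a.region.value, a.remoteness.value,
                        a.irsd_decile, a.indigenous_pct, a.population])
    with open(outdir / "facilities.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["facility_id", "name", "lon", "lat", "role"])
        for fid, f in sorted(bundle.facilities.items()):
            w.writerow([fid, f.name, repr(f.lon), repr(f.lat), f.role.value])
    with open(outdir / "travel_times.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["area_id", "facility_id", "hours"])
        for (aid, fid), hours in bundle.ttm.items():
            w.writerow([aid, fid, repr(hours)])
    write_patients(bundle.records, outdir / "patients.csv")
    with open(outdir / "concordance.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["postcode", "suburb", "area_id", "weight"])
        for row in conc_rows:
            w.writerow(row)
    with open(outdir / "diagnosis_map.csv", "w", newline="") as fh:
        w = _csv.writer(fh)
        w.writerow(["source_code", "standard_label"])
        for code, label in bundle.diagnosis_map.items():
            w.writerow([code, label])
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(bundle.config.to_dict(), fh, sort_keys=True)
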