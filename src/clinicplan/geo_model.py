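"""Domain types for small statistical areas, facilities and travel times.

The analysis unit is a small census-style statistical area (modelled on the
Australian SA2, ~10,000 persons) carrying sociodemographic attributes:
IRSD decile (1-10, lower = more disadvantaged), ARIA remoteness class,
Aboriginal and Torres Strait Islander population percentage, and total
population.  All driving times come from a precomputed origin-destination
matrix, never from geometry, so coordinates stay in WGS84 lon/lat and no
projected CRS is involved.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Union

from shapely.geometry import shape as _shapely_shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)


class Region(str, Enum):
    """Map-scoping regions: Greater Sydney, the ACT, and the rest of NSW."""

    GREATER_SYDNEY = "GreaterSydney"
    ACT = "ACT"
    REST_OF_STATE = "RestOfState"


class Remoteness(str, Enum):
    """The five ARIA remoteness categories."""

    MAJOR_CITIES = "MajorCities"
    INNER_REGIONAL = "InnerRegional"
    OUTER_REGIONAL = "OuterRegional"
    REMOTE = "Remote"
    VERY_REMOTE = "VeryRemote"


class FacilityRole(str, Enum):
    CURRENT_CLINIC = "current_clinic"
    CANDIDATE = "candidate"
    HOSPITAL = "hospital"


class ValidationError(ValueError):
    """Raised when an input file violates a domain invariant."""


@dataclass
class Area:
    """One small statistical area with sociodemographic attributes.

    ``geometry`` is an optional polygon (shapely, lon/lat).  ``irsd_decile``
    may be missing (None); when present it must lie in 1..10.
    """

    area_id: str
    name: str = ""
    region: Optional[Region] = None
    remoteness: Optional[Remoteness] = None
    irsd_decile: Optional[int] = None
    indigenous_pct: Optional[float] = None
    population: int = 0
    geometry: Optional[BaseGeometry] = None
    attributes_missing: bool = False

    def __post_init__(self) -> None:
        if self.irsd_decile is not None and not 1 <= int(self.irsd_decile) <= 10:
            raise ValidationError(
                f"area {self.area_id!r}: irsd_decile {self.irsd_decile} outside 1..10"
            )
        if self.indigenous_pct is not None and not 0.0 <= self.indigenous_pct <= 100.0:
            raise ValidationError(
                f"area {self.area_id!r}: indigenous_pct {self.indigenous_pct} outside 0..100"
            )
        if self.population < 0:
            raise ValidationError(f"area {self.area_id!r}: negative population")


@dataclass
class Facility:
    """A hospital or clinic site; ``role`` controls clinic-set eligibility."""

    facility_id: str
    name: str
    lon: float
    lat: float
    role: FacilityRole = FacilityRole.HOSPITAL


class AreaSet:
    """Ordered collection of :class:`Area`, unique by ``area_id``."""

    def __init__(self, areas: Iterable[Area]):
        self._areas: dict[str, Area] = {}
        for a in areas:
            if a.area_id in self._areas:
                raise ValidationError(f"duplicate area_id {a.area_id!r}")
            self._areas[a.area_id] = a

    def __len__(self) -> int:
        return len(self._areas)

    def __iter__(self) -> Iterator[Area]:
        return iter(self._areas.values())

    def __contains__(self, area_id: str) -> bool:
        return area_id in self._areas

    def __getitem__(self, area_id: str) -> Area:
        return self._areas[area_id]

    def get(self, area_id: str) -> Optional[Area]:
        return self._areas.get(area_id)

    @property
    def ids(self) -> list[str]:
        return list(self._areas)

    def in_region(self, region: Optional[Region]) -> list[Area]:
        """Areas in ``region``; ``None`` means all areas (the 'All' scope)."""
        if region is None:
            return list(self)
        return [a for a in self if a.region == region]


UNCOVERED = None  # sentinel meaning: no travel-time data for this lookup


class TravelTimeMatrix:
    """Sparse area x facility driving times in hours.

    Missingness is meaningful: an absent pair is reported as ``None``
    (never a default number), and an area with no entry for any facility
    is "uncovered" — the grey areas on the published maps.
    """

    def __init__(self, entries: Mapping[tuple[str, str], float]):
        self._entries: dict[tuple[str, str], float] = {}
        self._by_area: dict[str, dict[str, float]] = {}
        for (area_id, facility_id), hours in entries.items():
            if hours < 0:
                raise ValidationError(
                    f"negative driving time for ({area_id}, {facility_id}): {hours}"
                )
            key = (area_id, facility_id)
            if key in self._entries:
                raise ValidationError(f"duplicate travel-time pair {key}")
            self._entries[key] = float(hours)
            self._by_area.setdefault(area_id, {})[facility_id] = float(hours)

    def lookup(self, area_id: str, facility_id: str) -> Optional[float]:
        """Driving time in hours, or ``None`` when the pair is absent."""
        return self._entries.get((area_id, facility_id))

    def times_from(self, area_id: str) -> dict[str, float]:
        """All known facility times from one area (possibly empty)."""
        return dict(self._by_area.get(area_id, {}))

    def is_uncovered(self, area_id: str) -> bool:
        return not self._by_area.get(area_id)

    def __len__(self) -> int:
        return len(self._entries)

    def items(self) -> Iterator[tuple[tuple[str, str], float]]:
        return iter(self._entries.items())


@dataclass
class ClinicSet:
    """Ordered list of facility ids treated as open clinics (no duplicates)."""

    facility_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for fid in self.facility_ids:
            if fid in seen:
                raise ValidationError(f"duplicate facility_id {fid!r} in clinic set")
            seen.add(fid)

    def __len__(self) -> int:
        return len(self.facility_ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.facility_ids)

    def __contains__(self, fid: str) -> bool:
        return fid in self.facility_ids

    def union(self, other: "ClinicSet") -> "ClinicSet":
        return ClinicSet(list(self.facility_ids) + [f for f in other if f not in self])

    def validate_against(self, facilities: Mapping[str, Facility]) -> None:
        for fid in self.facility_ids:
            if fid not in facilities:
                raise ValidationError(f"clinic set references unknown facility {fid!r}")


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _parse_optional_int(raw: str) -> Optional[int]:
    raw = (raw or "").strip()
    return int(raw) if raw else None


def _parse_optional_float(raw: str) -> Optional[float]:
    raw = (raw or "").strip()
    return float(raw) if raw else None


def read_areas(geojson_path: Union[str, Path],
               attributes_csv_path: Union[str, Path]) -> AreaSet:
    """Load areas from a GeoJSON FeatureCollection joined to an attribute CSV.

    Each feature must carry an ``area_id`` property; the CSV is keyed by
    ``area_id`` with columns name, region, remoteness, irsd_decile,
    indigenous_pct, population.  Features without a CSV row are kept but
    flagged ``attributes_missing`` (with a warning); CSV rows without a
    feature are reported via a warning and dropped.
    """
    with open(geojson_path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValidationError("areas GeoJSON must be a FeatureCollection")

    attrs: dict[str, dict[str, str]] = {}
    with open(attributes_csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            aid = row["area_id"].strip()
            if aid in attrs:
                raise ValidationError(f"duplicate area_id {aid!r} in attribute CSV")
            attrs[aid] = row

    areas: list[Area] = []
    seen: set[str] = set()
    for feature in doc.get("features", []):
        props = feature.get("properties") or {}
        aid = props.get("area_id")
        if aid is None:
            raise ValidationError("GeoJSON feature missing area_id property")
        aid = str(aid)
        if aid in seen:
            raise ValidationError(f"duplicate area_id {aid!r} in GeoJSON")
        seen.add(aid)
        geom_obj = feature.get("geometry")
        geometry = None
        if geom_obj is not None:
            try:
                geometry = _shapely_shape(geom_obj)
                if not geometry.is_valid:
                    raise ValueError("invalid polygon")
            except Exception as exc:
                raise ValidationError(f"malformed geometry for area {aid!r}: {exc}") from exc
        row = attrs.pop(aid, None)
        if row is None:
            logger.warning("area %s present in GeoJSON but missing from attribute CSV", aid)
            areas.append(Area(area_id=aid, geometry=geometry, attributes_missing=True))
            continue
        areas.append(Area(
            area_id=aid,
            name=row.get("name", ""),
            region=Region(row["region"]) if row.get("region") else None,
            remoteness=Remoteness(row["remoteness"]) if row.get("remoteness") else None,
            irsd_decile=_parse_optional_int(row.get("irsd_decile", "")),
            indigenous_pct=_parse_optional_float(row.get("indigenous_pct", "")),
            population=int(row.get("population", 0) or 0),
            geometry=geometry,
        ))
    for aid in attrs:
        logger.warning("area %s present in attribute CSV but not in GeoJSON; dropped", aid)
    return AreaSet(areas)


def read_facilities(csv_path: Union[str, Path]) -> dict[str, Facility]:
    """Load the facility list (facility_id,name,lon,lat,role), keyed by id."""
    facilities: dict[str, Facility] = {}
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            fid = row["facility_id"].strip()
            if fid in facilities:
                raise ValidationError(f"duplicate facility_id {fid!r}")
            facilities[fid] = Facility(
                facility_id=fid,
                name=row.get("name", ""),
                lon=float(row["lon"]),
                lat=float(row["lat"]),
                role=FacilityRole(row.get("role", "hospital")),
            )
    return facilities


def read_travel_matrix(csv_path: Union[str, Path]) -> TravelTimeMatrix:
    """Load the long-format OD matrix CSV (area_id,facility_id,hours).

    Duplicate pairs and negative hours are hard errors.  Ids are retained
    as-is; validation against a particular AreaSet/facility list happens
    downstream.
    """
    entries: dict[tuple[str, str], float] = {}
    with open(csv_path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh), start=2):
            key = (row["area_id"].strip(), row["facility_id"].strip())
            if key in entries:
                raise ValidationError(f"duplicate travel-time pair {key} (line {i})")
            hours = float(row["hours"])
            if hours < 0:
                raise ValidationError(f"negative hours {hours} at line {i}")
            entries[key] = hours
    return TravelTimeMatrix(entries)


# ---------------------------------------------------------------------------
# Choropleth export
# ---------------------------------------------------------------------------

def write_choropleth(areas: AreaSet, values: Mapping[str, object], layer_name: str,
                     path: Optional[Union[str, Path]] = None) -> dict:
    """Build (and optionally write) a choropleth GeoJSON FeatureCollection.

    Every feature carries the area geometry plus a property ``layer_name``
    holding the area's value, the string ``"masked"`` for masked cells, or
    ``null`` for areas with no value.  Unknown area ids in ``values`` are a
    hard error.
    """
    from .privacy import Masked  # local import to avoid a cycle

    for aid in values:
        if aid not in areas:
            raise ValidationError(f"choropleth value for unknown area {aid!r}")
    features = []
    for area in areas:
        val = values.get(area.area_id)
        if isinstance(val, Masked):
            val = "masked"
        geom = None
        if area.geometry is not None:
            geom = json.loads(json.dumps(area.geometry.__geo_interface__))
        features.append({
            "type": "Feature",
            "properties": {"area_id": area.area_id, "name": area.name, layer_name: val},
            "geometry": geom,
        })
    doc = {"type": "FeatureCollection", "name": layer_name, "features": features}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    return doc
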