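"""Shared fixtures: a tiny hand-built world and randomized fixture builders."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest

from clinicplan.cohort import AreaAggregate, Severity, StudyWindow
from clinicplan.geo_model import (Area, AreaSet, Region, Remoteness,
                                  TravelTimeMatrix)
from clinicplan.synthetic_data import GeneratorConfig, generate_bundle

WINDOW = StudyWindow(date(2000, 1, 1), date(2022, 7, 1))

REGIONS = [Region.GREATER_SYDNEY, Region.ACT, Region.REST_OF_STATE]


@pytest.fixture
def window() -> StudyWindow:
    return WINDOW


@pytest.fixture
def tiny_areas() -> AreaSet:
    return AreaSet([
        Area("A1", "Alpha", Region.GREATER_SYDNEY, Remoteness.MAJOR_CITIES,
             irsd_decile=3, indigenous_pct=2.0, population=9000),
        Area("A2", "Beta", Region.GREATER_SYDNEY, Remoteness.INNER_REGIONAL,
             irsd_decile=7, indigenous_pct=5.0, population=11000),
        Area("A3", "Gamma", Region.REST_OF_STATE, Remoteness.OUTER_REGIONAL,
             irsd_decile=1, indigenous_pct=12.0, population=8000),
        Area("A4", "Delta", Region.REST_OF_STATE, Remoteness.REMOTE,
             irsd_decile=5, indigenous_pct=20.0, population=4000),
    ])


def make_world(rng: np.random.Generator, max_areas: int = 50, max_facilities: int = 10,
               pair_missing_p: float = 0.0, area_uncovered_p: float = 0.1):
    """Random small world: areas with aggregates, facilities and a matrix.

    Missingness is area-level by default (an uncovered area has no entry for
    any facility, like the real driving-time dataset's grey areas); per-pair
    gaps can be added for lookup-path tests via ``pair_missing_p``.
    """
    n_areas = int(rng.integers(2, max_areas + 1))
    n_fac = int(rng.integers(1, max_facilities + 1))
    areas = AreaSet([
        Area(f"A{i:03d}", f"Area {i}", REGIONS[int(rng.integers(0, 3))],
             Remoteness.MAJOR_CITIES, population=1000)
        for i in range(n_areas)
    ])
    fids = [f"F{j:02d}" for j in range(n_fac)]
    entries = {}
    for a in areas:
        if rng.random() < area_uncovered_p:
            continue
        for fid in fids:
            if rng.random() < pair_missing_p:
                continue
            entries[(a.area_id, fid)] = float(rng.uniform(0.0, 10.0))
    ttm = TravelTimeMatrix(entries)
    aggregates = []
    for a in areas:
        n = int(rng.integers(0, 21))
        ltf = int(rng.integers(0, n + 1)) if n else 0
        sev = rng.multinomial(n, [0.4, 0.3, 0.15, 0.15])
        aggregates.append(AreaAggregate(
            area_id=a.area_id, n_patients=n,
            n_by_severity=dict(zip(Severity, (int(x) for x in sev))),
            n_lost_to_follow_up=ltf,
            diagnosis_counts={"Dx": int(rng.integers(0, n + 1))} if n else {},
        ))
    return areas, fids, ttm, aggregates


def brute_force_nearest(area_id: str, clinics, ttm: TravelTimeMatrix):
    """Independent oracle: exhaustive scan with the stated tie-break."""
    candidates = [(ttm.lookup(area_id, fid), fid) for fid in clinics
                  if ttm.lookup(area_id, fid) is not None]
    if not candidates:
        return None, None
    best = min(candidates, key=lambda c: (c[0], c[1]))
    return best[1], best[0]


@pytest.fixture(scope="session")
def default_bundle():
    """The full-size default synthetic world (seeded once per session)."""
    return generate_bundle(GeneratorConfig(seed=1234))


@pytest.fixture(scope="session")
def small_bundle():
    """A compact world for fast end-to-end tests."""
    cfg = GeneratorConfig(seed=99, n_areas=48, grid_cols=8, cohort_size=400,
                          n_facilities=12, n_current_clinics=2)
    return generate_bundle(cfg)
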