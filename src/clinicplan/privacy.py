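"""Small-cell suppression for the public branch of the planning tool.

Two branches exist: a *private* branch with full patient-level counts, and a
*public* branch in which any displayed geographic patient count below the
threshold (default five individuals) is replaced by a masked sentinel.
Zeros are displayed — a zero describes no individual.  Where a breakdown
(e.g. counts by disease severity) is published next to its total, masking a
single small cell would let it be recovered by subtraction, so the smallest
remaining non-zero sibling is masked too (complementary suppression).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

from .geo_model import ValidationError


class Masked:
    """Singleton sentinel for a suppressed count; serializes as "masked"."""

    _instance: Optional["Masked"] = None

    def __new__(cls) -> "Masked":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "masked"

    def __str__(self) -> str:
        return "masked"


MASKED = Masked()


class MaskMode(str, Enum):
    PRIVATE = "private"
    PUBLIC = "public"


@dataclass(frozen=True)
class MaskPolicy:
    """Masking configuration; private mode is the identity transform."""

    threshold: int = 5
    mode: MaskMode = MaskMode.PRIVATE
    mask_clinic_tables: bool = True  # also mask per-clinic Patients/ltf cells

    def __post_init__(self) -> None:
        if self.threshold < 2:
            raise ValidationError("mask threshold must be >= 2")

    @property
    def active(self) -> bool:
        return self.mode == MaskMode.PUBLIC


def _mask_count(c, threshold: int):
    if isinstance(c, Masked):
        return MASKED
    if 0 < int(c) < threshold:
        return MASKED
    return c


def _suppress_group(cells: dict, total, threshold: int) -> dict:
    """Primary suppression of a breakdown plus complementary suppression.

    If the group's total is displayed and exactly one cell is masked, that
    cell equals total minus the displayed cells — so the smallest remaining
    non-zero cell is masked as well.
    """
    out = {k: _mask_count(v, threshold) for k, v in cells.items()}
    total_displayed = not isinstance(_mask_count(total, threshold), Masked)
    masked_keys = [k for k, v in out.items() if isinstance(v, Masked)]
    if total_displayed and len(masked_keys) == 1:
        unmasked_nonzero = [(int(v), k) for k, v in out.items()
                            if not isinstance(v, Masked) and int(v) > 0]
        if unmasked_nonzero:
            _, key = min(unmasked_nonzero)
            out[key] = MASKED
    return out


def mask_aggregates(aggregates: Sequence, policy: MaskPolicy) -> list:
    """Apply the masking policy to per-area aggregates.

    Public mode: every count in (0, threshold) — total, per-severity,
    per-diagnosis, lost-to-follow-up — becomes the masked sentinel, with
    complementary suppression on the severity/total split.  Private mode
    returns (copies of) the input unchanged.  Idempotent.
    """
    masked = [copy.deepcopy(a) for a in aggregates]
    if not policy.active:
        return masked
    for agg in masked:
        total = agg.n_patients
        agg.n_by_severity = _suppress_group(agg.n_by_severity, total, policy.threshold)
        # diagnosis counts have no displayed total constraint (multi-diagnosis
        # patients make their sum exceed n), so primary suppression suffices
        agg.diagnosis_counts = {k: _mask_count(v, policy.threshold)
                                for k, v in agg.diagnosis_counts.items()}
        agg.n_lost_to_follow_up = _mask_count(agg.n_lost_to_follow_up, policy.threshold)
        agg.n_patients = _mask_count(total, policy.threshold)
        agg.masked = any(isinstance(v, Masked) for v in
                         [agg.n_patients, agg.n_lost_to_follow_up,
                          *agg.n_by_severity.values(), *agg.diagnosis_counts.values()])
    return masked


def mask_layer(layer: Mapping[str, object], policy: MaskPolicy,
               layer_kind: str = "count") -> dict[str, object]:
    """Mask a choropleth layer.

    Patient-count layers (``layer_kind="count"``) are masked like aggregate
    counts; drive-time layers (``"time"``) carry no patient information and
    pass through untouched in every mode.
    """
    if layer_kind not in ("count", "time"):
        raise ValidationError(f"unknown layer kind {layer_kind!r}")
    if layer_kind == "time" or not policy.active:
        return dict(layer)
    out: dict[str, object] = {}
    for aid, val in layer.items():
        if val is None or isinstance(val, Masked):
            out[aid] = val if val is None else MASKED
        else:
            out[aid] = _mask_count(val, policy.threshold)
    return out


def mask_clinic_rows(rows: Sequence, policy: MaskPolicy) -> list:
    """Mask per-clinic Patients/ltf cells when the policy says to."""
    from .accessibility import ClinicTableRow

    if not (policy.active and policy.mask_clinic_tables):
        return list(rows)
    out = []
    for row in rows:
        out.append(ClinicTableRow(
            facility_id=row.facility_id,
            n_patients_within_threshold=_mask_count(
                row.n_patients_within_threshold, policy.threshold),
            n_ltf_within_threshold=_mask_count(
                row.n_ltf_within_threshold, policy.threshold),
        ))
    return out


def serialize_count(value) -> object:
    """JSON/CSV representation of a maybe-masked count."""
    return "masked" if isinstance(value, Masked) else value
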