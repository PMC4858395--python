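"""Normalized data model for uterotrophic study-protocol records.

A *uterotrophic bioassay* detects estrogen-receptor agonism as a
statistically significant increase in rodent uterine weight.  Each
:class:`StudyRecord` captures one chemical/study/protocol combination as
curated from a publication: animal model, dosing regimen, group sizes,
necropsy timing, and the outcome together with its dose anchor — the
lowest effect level (LEL) for active outcomes or the highest dose tested
(HDT) for inactive ones.

Doses carry explicit units.  Comparing doses expressed in different units
is refused rather than silently coerced: a dose in mg per animal per day
cannot be ranked against one in mg/kg/day without a body weight.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, fields, replace
from typing import Iterable, Optional


class DoseUnit(str, enum.Enum):
    """Controlled vocabulary for dose units."""

    MG_PER_KG_PER_DAY = "mg/kg/day"
    MG_PER_ANIMAL_PER_DAY = "mg/animal/day"
    OTHER = "other"


class Species(str, enum.Enum):
    RAT = "rat"
    MOUSE = "mouse"


class StudyType(str, enum.Enum):
    IMMATURE = "immature"
    OVX = "ovx"
    INTACT = "intact"
    OTHER = "other"


class Route(str, enum.Enum):
    SC = "sc"
    IP = "ip"
    PO = "po"
    OTHER = "other"


class Outcome(str, enum.Enum):
    ACTIVE = "active"
    INACTIVE = "inactive"


class ResponseDirection(str, enum.Enum):
    INCREASE = "increase"
    DECREASE = "decrease"
    NONE = "none"
    UNREPORTED = "unreported"


class UnitMismatchError(ValueError):
    """Raised when doses in different units are compared."""


@dataclass(frozen=True)
class Dose:
    """A dose with an explicit unit.

    ``original_unit`` retains the free-text unit string from the source
    table; ``non_normalizable`` marks a per-animal dose that could not be
    converted to mg/kg/day for lack of a body weight.
    """

    value: float
    unit: DoseUnit
    original_unit: str = ""
    non_normalizable: bool = False

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"dose value must be non-negative, got {self.value}")
        if not isinstance(self.unit, DoseUnit):
            raise TypeError(f"unit must be a DoseUnit, got {self.unit!r}")

    def same_unit(self, other: "Dose") -> bool:
        return self.unit is other.unit

    def __lt__(self, other: "Dose") -> bool:
        if not self.same_unit(other):
            raise UnitMismatchError(
                f"cannot compare doses in {self.unit.value} and {other.unit.value}"
            )
        return self.value < other.value

    def __le__(self, other: "Dose") -> bool:
        if not self.same_unit(other):
            raise UnitMismatchError(
                f"cannot compare doses in {self.unit.value} and {other.unit.value}"
            )
        return self.value <= other.value


def min_dose(doses: Iterable[Dose]) -> Optional[Dose]:
    """Minimum of same-unit doses; refuses mixed units; None for empty."""
    doses = list(doses)
    if not doses:
        return None
    units = {d.unit for d in doses}
    if len(units) > 1:
        raise UnitMismatchError(f"mixed units in minimum: {sorted(u.value for u in units)}")
    return min(doses, key=lambda d: d.value)


def max_dose(doses: Iterable[Dose]) -> Optional[Dose]:
    """Maximum of same-unit doses; refuses mixed units; None for empty."""
    doses = list(doses)
    if not doses:
        return None
    units = {d.unit for d in doses}
    if len(units) > 1:
        raise UnitMismatchError(f"mixed units in maximum: {sorted(u.value for u in units)}")
    return max(doses, key=lambda d: d.value)


def normalize_dose(d: Dose, body_weight_kg: Optional[float] = None) -> Dose:
    """Convert a per-animal dose to mg/kg/day when a body weight is known.

    mg/kg/day doses pass through unchanged (idempotent).  A per-animal
    dose with no body weight is returned unchanged but flagged
    ``non_normalizable``; units outside the two named conventions are
    likewise flagged.
    """
    if body_weight_kg is not None and body_weight_kg <= 0:
        raise ValueError(f"body_weight_kg must be positive, got {body_weight_kg}")
    if d.unit is DoseUnit.MG_PER_KG_PER_DAY:
        return d
    if d.unit is DoseUnit.MG_PER_ANIMAL_PER_DAY and body_weight_kg is not None:
        return Dose(
            value=d.value / body_weight_kg,
            unit=DoseUnit.MG_PER_KG_PER_DAY,
            original_unit=d.original_unit or DoseUnit.MG_PER_ANIMAL_PER_DAY.value,
        )
    return replace(d, non_normalizable=True)


_CASRN_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")


def casrn_checksum_ok(casrn: str) -> bool:
    """Validate a CAS Registry Number's format and check digit."""
    m = _CASRN_RE.match(casrn)
    if not m:
        return False
    digits = (m.group(1) + m.group(2))[::-1]
    total = sum((i + 1) * int(c) for i, c in enumerate(digits))
    return total % 10 == int(m.group(3))


def make_casrn(base: int) -> str:
    """Build a checksum-valid synthetic CASRN from an integer stem."""
    body = f"{base:06d}"
    stem, mid = body[:-2], body[-2:]
    digits = (stem + mid)[::-1]
    check = sum((i + 1) * int(c) for i, c in enumerate(digits)) % 10
    return f"{stem}-{mid}-{check}"


@dataclass
class StudyRecord:
    """One chemical/study/protocol combination from the curated database."""

    record_id: str
    publication_id: str
    casrn: str
    chemical_name: str
    species: Species
    study_type: StudyType
    route: Route
    outcome: Outcome
    strain: str = ""
    route_original: str = ""
    dose_start_pnd: Optional[int] = None
    is_adult: bool = False
    ovx_age_weeks: Optional[float] = None
    days_post_ovx_before_dosing: Optional[int] = None
    dosing_length_days: Optional[int] = None
    dosing_consecutive: bool = False
    n_dose_groups: int = 0
    highest_dose: Optional[Dose] = None
    n_control_animals: Optional[int] = None
    n_test_animals_min: Optional[int] = None
    necropsy_hr_after_last_dose: Optional[float] = None
    lel: Optional[Dose] = None
    response_direction: ResponseDirection = ResponseDirection.UNREPORTED
    is_positive_control_substance: bool = False
    is_mixture: bool = False
    phytoestrogen_diet_reported: bool = False
    assay_notes: str = ""
    response_notes: str = ""

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty if the record is valid)."""
        issues: list[str] = []
        if not _CASRN_RE.match(self.casrn):
            issues.append(f"casrn: malformed CASRN {self.casrn!r}")
        if self.outcome is Outcome.ACTIVE and self.lel is None:
            issues.append("lel: active outcome requires a reported LEL")
        if self.outcome is Outcome.INACTIVE and self.highest_dose is None:
            issues.append("highest_dose: inactive outcome requires a reported HDT")
        if (
            self.lel is not None
            and self.highest_dose is not None
            and self.lel.same_unit(self.highest_dose)
            and self.lel.value > self.highest_dose.value
        ):
            issues.append("lel: LEL exceeds the highest dose tested")
        if self.study_type is StudyType.IMMATURE and (
            self.ovx_age_weeks is not None or self.days_post_ovx_before_dosing is not None
        ):
            issues.append("ovx_age_weeks: OVX fields set on an immature-model study")
        for name in ("dosing_length_days", "n_control_animals", "n_test_animals_min"):
            v = getattr(self, name)
            if v is not None and v < 0:
                issues.append(f"{name}: negative count {v}")
        if self.dosing_length_days is not None and self.dosing_length_days < 1:
            issues.append(f"dosing_length_days: must be >= 1, got {self.dosing_length_days}")
        if self.n_dose_groups < 0:
            issues.append(f"n_dose_groups: negative count {self.n_dose_groups}")
        return issues


def record_field_names() -> list[str]:
    return [f.name for f in fields(StudyRecord)]
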