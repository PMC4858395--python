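"""Delimited-file I/O for study records.

The on-disk format is a UTF-8 CSV (or TSV, chosen by file extension) with
one row per study protocol and a fixed documented header.  Controlled
vocabularies are matched case-insensitively with a small alias map for
the spellings common in the literature ("s.c.", "p.o.", "gavage", ...).
In lenient mode unknown vocabulary tokens coerce to ``other`` with a
logged warning; in strict mode any schema violation raises
:class:`SchemaError` naming the row and field.

Necropsy and dosing-interval times written as short literature phrases
("24 hr", "1 day", "1 week") are resolved by a documented alias map
(day = 24 hr, week = 7 days); arbitrary free-text parsing is out of scope.
"""

from __future__ import annotations

import csv
import logging
import math
import os
from typing import Optional

from .records import (
    Dose,
    DoseUnit,
    Outcome,
    ResponseDirection,
    Route,
    Species,
    StudyRecord,
    StudyType,
    casrn_checksum_ok,
)

log = logging.getLogger(__name__)

COLUMNS = [
    "record_id",
    "publication_id",
    "casrn",
    "chemical_name",
    "species",
    "strain",
    "study_type",
    "route",
    "dose_start_pnd",
    "is_adult",
    "ovx_age_weeks",
    "days_post_ovx_before_dosing",
    "dosing_length_days",
    "dosing_consecutive",
    "n_dose_groups",
    "highest_dose_value",
    "highest_dose_unit",
    "n_control_animals",
    "n_test_animals_min",
    "necropsy_hr_after_last_dose",
    "outcome",
    "lel_value",
    "lel_unit",
    "response_direction",
    "is_positive_control_substance",
    "is_mixture",
    "phytoestrogen_diet_reported",
    "assay_notes",
    "response_notes",
]

MANDATORY = {"record_id", "publication_id", "casrn", "chemical_name", "species",
             "study_type", "route", "outcome"}

_SPECIES_ALIASES = {"rat": Species.RAT, "rats": Species.RAT,
                    "mouse": Species.MOUSE, "mice": Species.MOUSE}
_STUDY_TYPE_ALIASES = {"immature": StudyType.IMMATURE, "ovx": StudyType.OVX,
                       "ovariectomized": StudyType.OVX, "intact": StudyType.INTACT,
                       "other": StudyType.OTHER}
_ROUTE_ALIASES = {"sc": Route.SC, "s.c.": Route.SC, "subcutaneous": Route.SC,
                  "ip": Route.IP, "i.p.": Route.IP, "intraperitoneal": Route.IP,
                  "po": Route.PO, "p.o.": Route.PO, "oral gavage": Route.PO,
                  "gavage": Route.PO, "other": Route.OTHER}
_UNIT_ALIASES = {"mg/kg/day": DoseUnit.MG_PER_KG_PER_DAY,
                 "mg/kg/d": DoseUnit.MG_PER_KG_PER_DAY,
                 "mg per kg per day": DoseUnit.MG_PER_KG_PER_DAY,
                 "mg/animal/day": DoseUnit.MG_PER_ANIMAL_PER_DAY,
                 "mg/animal": DoseUnit.MG_PER_ANIMAL_PER_DAY,
                 "mg/rat/day": DoseUnit.MG_PER_ANIMAL_PER_DAY,
                 "mg/mouse/day": DoseUnit.MG_PER_ANIMAL_PER_DAY}
_TRUE_TOKENS = {"true", "1", "yes", "y", "t"}
_FALSE_TOKENS = {"false", "0", "no", "n", "f", ""}

# Literature phrasings for times: "1 day" is taken as exactly 24 hr.
_HOUR_PER = {"hr": 1.0, "hrs": 1.0, "h": 1.0, "hour": 1.0, "hours": 1.0,
             "day": 24.0, "days": 24.0, "d": 24.0,
             "week": 168.0, "weeks": 168.0, "wk": 168.0}


class SchemaError(ValueError):
    """A strict-mode schema violation, carrying row/field diagnostics."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("schema errors:\n" + "\n".join(problems))


def _delimiter_for(path: str) -> str:
    return "\t" if os.fspath(path).lower().endswith(".tsv") else ","


def parse_hours(text: str) -> Optional[float]:
    """Parse '24', '24 hr' or '1 day' into hours; None for blank."""
    text = text.strip()
    if not text:
        return None
    parts = text.split()
    if len(parts) == 1:
        return float(parts[0])
    if len(parts) == 2 and parts[1].lower() in _HOUR_PER:
        return float(parts[0]) * _HOUR_PER[parts[1].lower()]
    raise ValueError(f"unparseable time {text!r}")


class _RowReader:
    def __init__(self, strict: bool):
        self.strict = strict
        self.problems: list[str] = []
        self.rownum = 0

    def problem(self, field: str, msg: str) -> None:
        self.problems.append(f"row {self.rownum}, {field}: {msg}")

    def enum(self, row, field, aliases, fallback):
        raw = row.get(field, "").strip()
        key = raw.lower()
        if key in aliases:
            return aliases[key], raw
        if self.strict and field in ("species", "outcome"):
            self.problem(field, f"unknown token {raw!r}")
            return fallback, raw
        if raw:
            log.warning("row %d: %s token %r mapped to %r", self.rownum, field, raw,
                        fallback.value)
        return fallback, raw

    def number(self, row, field, conv):
        raw = row.get(field, "").strip()
        if not raw:
            return None
        try:
            v = conv(raw)
        except ValueError:
            self.problem(field, f"not a number: {raw!r}")
            return None
        return v

    def boolean(self, row, field):
        raw = row.get(field, "").strip().lower()
        if raw in _TRUE_TOKENS:
            return True
        if raw in _FALSE_TOKENS:
            return False
        self.problem(field, f"not a boolean: {raw!r}")
        return False

    def dose(self, row, value_field, unit_field):
        raw = row.get(value_field, "").strip()
        if not raw:
            return None
        value = self.number(row, value_field, float)
        if value is None or value < 0:
            if value is not None:
                self.problem(value_field, f"negative dose {value}")
            return None
        raw_unit = row.get(unit_field, "").strip()
        unit = _UNIT_ALIASES.get(raw_unit.lower(), DoseUnit.OTHER)
        if unit is DoseUnit.OTHER and raw_unit.lower() not in ("", "other"):
            log.warning("row %d: dose unit %r retained as 'other'", self.rownum, raw_unit)
        return Dose(value=value, unit=unit, original_unit=raw_unit)


def read_records(path: str, strict: bool = False) -> list[StudyRecord]:
    """Read study records from a delimited file.

    In strict mode, malformed CASRNs, negative counts, unknown mandatory
    vocabulary, invariant violations and missing mandatory columns raise
    a :class:`SchemaError` listing every offending row and field.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter_for(path))
        header = reader.fieldnames or []
        missing = [c for c in COLUMNS if c not in header]
        if missing and strict:
            raise SchemaError([f"header: missing mandatory columns {missing}"])
        rr = _RowReader(strict)
        records: list[StudyRecord] = []
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            rr.rownum = i
            species, _ = rr.enum(row, "species", _SPECIES_ALIASES, Species.RAT)
            study_type, _ = rr.enum(row, "study_type", _STUDY_TYPE_ALIASES, StudyType.OTHER)
            route, route_raw = rr.enum(row, "route", _ROUTE_ALIASES, Route.OTHER)
            outcome_raw = row.get("outcome", "").strip().lower()
            if outcome_raw == "active":
                outcome = Outcome.ACTIVE
            elif outcome_raw == "inactive":
                outcome = Outcome.INACTIVE
            else:
                rr.problem("outcome", f"unknown token {outcome_raw!r}")
                outcome = Outcome.INACTIVE
            direction_raw = row.get("response_direction", "").strip().lower()
            direction = {d.value: d for d in ResponseDirection}.get(
                direction_raw, ResponseDirection.UNREPORTED)
            try:
                necropsy = parse_hours(row.get("necropsy_hr_after_last_dose", ""))
            except ValueError as e:
                rr.problem("necropsy_hr_after_last_dose", str(e))
                necropsy = None
            rec = StudyRecord(
                record_id=row.get("record_id", "").strip(),
                publication_id=row.get("publication_id", "").strip(),
                casrn=row.get("casrn", "").strip(),
                chemical_name=row.get("chemical_name", "").strip(),
                species=species,
                strain=row.get("strain", ""),
                study_type=study_type,
                route=route,
                route_original=route_raw,
                dose_start_pnd=rr.number(row, "dose_start_pnd", int),
                is_adult=rr.boolean(row, "is_adult"),
                ovx_age_weeks=rr.number(row, "ovx_age_weeks", float),
                days_post_ovx_before_dosing=rr.number(row, "days_post_ovx_before_dosing", int),
                dosing_length_days=rr.number(row, "dosing_length_days", int),
                dosing_consecutive=rr.boolean(row, "dosing_consecutive"),
                n_dose_groups=rr.number(row, "n_dose_groups", int) or 0,
                highest_dose=rr.dose(row, "highest_dose_value", "highest_dose_unit"),
                n_control_animals=rr.number(row, "n_control_animals", int),
                n_test_animals_min=rr.number(row, "n_test_animals_min", int),
                necropsy_hr_after_last_dose=necropsy,
                outcome=outcome,
                lel=rr.dose(row, "lel_value", "lel_unit"),
                response_direction=direction,
                is_positive_control_substance=rr.boolean(row, "is_positive_control_substance"),
                is_mixture=rr.boolean(row, "is_mixture"),
                phytoestrogen_diet_reported=rr.boolean(row, "phytoestrogen_diet_reported"),
                assay_notes=row.get("assay_notes", ""),
                response_notes=row.get("response_notes", ""),
            )
            if strict:
                for issue in rec.validate():
                    # CASRN checksum failures only warn: the source tables
                    # are authoritative even for a transcribed CASRN.
                    rr.problem(issue.split(":")[0], issue.split(": ", 1)[1])
            if not casrn_checksum_ok(rec.casrn):
                log.warning("row %d: CASRN %r fails checksum", i, rec.casrn)
            records.append(rec)
        if strict and rr.problems:
            raise SchemaError(rr.problems)
    return records


def _fmt_num(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        if math.isfinite(v) and v == int(v) and abs(v) < 1e15:
            return str(int(v))
        return repr(v)
    return str(v)


def _fmt_bool(v: bool) -> str:
    return "true" if v else "false"


def record_to_row(r: StudyRecord) -> dict[str, str]:
    return {
        "record_id": r.record_id,
        "publication_id": r.publication_id,
        "casrn": r.casrn,
        "chemical_name": r.chemical_name,
        "species": r.species.value,
        "strain": r.strain,
        "study_type": r.study_type.value,
        "route": r.route_original if r.route_original else r.route.value,
        "dose_start_pnd": _fmt_num(r.dose_start_pnd),
        "is_adult": _fmt_bool(r.is_adult),
        "ovx_age_weeks": _fmt_num(r.ovx_age_weeks),
        "days_post_ovx_before_dosing": _fmt_num(r.days_post_ovx_before_dosing),
        "dosing_length_days": _fmt_num(r.dosing_length_days),
        "dosing_consecutive": _fmt_bool(r.dosing_consecutive),
        "n_dose_groups": _fmt_num(r.n_dose_groups),
        "highest_dose_value": _fmt_num(r.highest_dose.value if r.highest_dose else None),
        "highest_dose_unit": (r.highest_dose.original_unit or r.highest_dose.unit.value)
                             if r.highest_dose else "",
        "n_control_animals": _fmt_num(r.n_control_animals),
        "n_test_animals_min": _fmt_num(r.n_test_animals_min),
        "necropsy_hr_after_last_dose": _fmt_num(r.necropsy_hr_after_last_dose),
        "outcome": r.outcome.value,
        "lel_value": _fmt_num(r.lel.value if r.lel else None),
        "lel_unit": (r.lel.original_unit or r.lel.unit.value) if r.lel else "",
        "response_direction": r.response_direction.value,
        "is_positive_control_substance": _fmt_bool(r.is_positive_control_substance),
        "is_mixture": _fmt_bool(r.is_mixture),
        "phytoestrogen_diet_reported": _fmt_bool(r.phytoestrogen_diet_reported),
        "assay_notes": r.assay_notes,
        "response_notes": r.response_notes,
    }


def write_records(records: list[StudyRecord], path: str) -> None:
    """Write records to CSV/TSV; read_records round-trips the result."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=COLUMNS, delimiter=_delimiter_for(path))
        writer.writeheader()
        for r in records:
            writer.writerow(record_to_row(r))
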