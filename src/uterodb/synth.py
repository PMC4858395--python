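"""Synthetic study populations and reference-table fixtures.

Two kinds of test inputs, neither requiring any download:

* :func:`generate` simulates a population of chemicals with latent
  uterotrophic potency tested under the six GL study designs, with
  design-dependent sensitivity, log-spaced dose grids of at most four
  doses, and protocol-compliance violations planted at configurable
  per-criterion rates.  A ground-truth ledger records every planted
  violation and each chemical's latent state, so downstream filters and
  summaries can be checked exactly.

* ``fixture_from_*`` builders reconstruct minimal GL-compliant record
  sets that realize published summary rows exactly — design-by-outcome
  counts, or per-chemical active/inactive counts with minLEL and maxHDT
  — so the aggregation stages invert them.

The packaged reference tables (``load_*``) carry the published
design-outcome counts of the curated GL uterotrophic database, its 18
discordant chemicals, and its 36 independently reproduced chemicals.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .records import (
    Dose,
    DoseUnit,
    Outcome,
    Route,
    Species,
    StudyRecord,
    StudyType,
    make_casrn,
)
from .concordance import DESIGN_BY_LABEL, DESIGN_ORDER, StudyDesign

# Atomic compliance criteria the generator can violate, with the design
# classes ("immature"/"ovx") each one applies to.
ATOMIC_CRITERIA = {
    "animal_model": ("immature", "ovx"),
    "immature_start_window": ("immature",),
    "immature_completion": ("immature",),
    "ovx_age_window": ("ovx",),
    "ovx_recovery_time": ("ovx",),
    "control_group_size": ("immature", "ovx"),
    "test_group_size": ("immature", "ovx"),
    "route": ("immature", "ovx"),
    "dose_group_count": ("immature", "ovx"),
    "dosing_interval": ("immature", "ovx"),
    "necropsy_window": ("immature", "ovx"),
}

# Default per-design probability that a truly estrogenic chemical tested
# within its dose range yields an active call, and default design
# frequencies; both follow the published GL design-outcome distribution.
DEFAULT_DESIGN_SENSITIVITY = {
    "Imm_Rat_Inj": 0.72, "Imm_Rat_Oral": 0.75, "OVX_Rat_Inj": 0.91,
    "OVX_Rat_Oral": 0.50, "OVX_Mouse_Inj": 0.44, "OVX_Mouse_Oral": 0.27,
}
DEFAULT_DESIGN_WEIGHTS = {
    "Imm_Rat_Inj": 204, "Imm_Rat_Oral": 81, "OVX_Rat_Inj": 32,
    "OVX_Rat_Oral": 10, "OVX_Mouse_Inj": 25, "OVX_Mouse_Oral": 22,
}

MKD = DoseUnit.MG_PER_KG_PER_DAY


@dataclass
class SynthConfig:
    """Parameters of the synthetic study-population generator.

    Potency is the lowest dose (mg/kg/day) at which a latently active
    chemical responds, sampled log-uniformly: published minLEL/maxHDT
    values span more than seven orders of magnitude.  ``dose_grid`` is a
    master log-spaced ladder; each study uses a contiguous window of at
    most ``max_doses_per_study`` rungs.  ``studies_per_chemical`` is
    either a fixed integer or ``("geometric", p)`` for a shifted
    geometric count (skewed, as real testing frequency is).
    """

    n_chemicals: int = 118
    p_true_active: float = 0.6
    potency_log10_range: tuple[float, float] = (-5.0, 3.0)
    design_sensitivity: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_DESIGN_SENSITIVITY))
    design_weights: dict[str, float] = dc_field(
        default_factory=lambda: dict(DEFAULT_DESIGN_WEIGHTS))
    dose_grid: tuple[float, ...] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)
    max_doses_per_study: int = 4
    studies_per_chemical: Union[int, tuple[str, float]] = ("geometric", 0.45)
    violation_rates: dict[str, float] = dc_field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_chemicals < 1:
            raise ValueError("n_chemicals must be >= 1")
        probs = [self.p_true_active, *self.design_sensitivity.values(),
                 *self.violation_rates.values()]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if list(self.dose_grid) != sorted(set(self.dose_grid)):
            raise ValueError("dose_grid must be strictly increasing")
        if not 2 <= self.max_doses_per_study <= 4:
            raise ValueError("studies use between 2 and 4 doses")
        for k in self.violation_rates:
            if k not in ATOMIC_CRITERIA:
                raise ValueError(f"unknown criterion {k!r}")
        for k in self.design_sensitivity:
            if k not in DESIGN_BY_LABEL:
                raise ValueError(f"unknown design {k!r}")


@dataclass
class GroundTruth:
    """Per-record planted violations and per-chemical latent state."""

    records: pd.DataFrame   # record_id, casrn, design, violations (';'-joined)
    chemicals: pd.DataFrame  # casrn, truly_active, potency_mg_per_kg


def _compliant_record(
    record_id: str, publication_id: str, casrn: str, name: str,
    design: StudyDesign, outcome: Outcome, lel: Optional[Dose],
    highest_dose: Optional[Dose], n_dose_groups: int = 3,
) -> StudyRecord:
    """A record passing every GL criterion, with canonical in-window fields."""
    immature = design.maturity == "immature"
    return StudyRecord(
        record_id=record_id,
        publication_id=publication_id,
        casrn=casrn,
        chemical_name=name,
        species=design.species,
        study_type=StudyType.IMMATURE if immature else StudyType.OVX,
        route=Route.SC if design.route_class == "injection" else Route.PO,
        dose_start_pnd=20 if immature else None,
        is_adult=not immature,
        ovx_age_weeks=None if immature else 7.0,
        days_post_ovx_before_dosing=None if immature else 14,
        dosing_length_days=3,
        dosing_consecutive=True,
        n_dose_groups=n_dose_groups,
        highest_dose=highest_dose,
        n_control_animals=3,
        n_test_animals_min=6,
        necropsy_hr_after_last_dose=24.0,
        outcome=outcome,
        lel=lel,
    )


def _plant_violation(r: StudyRecord, criterion: str, rng: np.random.Generator) -> None:
    """Mutate one field strictly outside its compliance window."""
    if criterion == "animal_model":
        if r.study_type is StudyType.IMMATURE:
            r.species = Species.MOUSE
        else:
            r.is_adult = False
    elif criterion == "immature_start_window":
        r.dose_start_pnd = int(rng.choice([16, 17, 26]))
    elif criterion == "immature_completion":
        r.dosing_length_days = 9  # ends PND 28 from a PND 20 start
    elif criterion == "ovx_age_window":
        r.ovx_age_weeks = float(rng.choice([4.0, 10.0]))
    elif criterion == "ovx_recovery_time":
        need = 14 if r.species is Species.RAT else 7
        r.days_post_ovx_before_dosing = int(rng.integers(0, need))
    elif criterion == "control_group_size":
        r.n_control_animals = int(rng.integers(0, 3))
    elif criterion == "test_group_size":
        r.n_test_animals_min = int(rng.integers(1, 5))
    elif criterion == "route":
        r.route = Route.OTHER
        r.route_original = "diet"
    elif criterion == "dose_group_count":
        r.n_dose_groups = 1
    elif criterion == "dosing_interval":
        if rng.random() < 0.5:
            r.dosing_length_days = int(rng.integers(1, 3))
        else:
            r.dosing_consecutive = False
    elif criterion == "necropsy_window":
        r.necropsy_hr_after_last_dose = float(rng.choice([6.0, 48.0]))
    else:  # pragma: no cover
        raise ValueError(f"unknown criterion {criterion!r}")


def generate(config: SynthConfig) -> tuple[list[StudyRecord], GroundTruth]:
    """Simulate a study-record population with a ground-truth ledger.

    A study's outcome is active iff the chemical is latently active, the
    design-sensitivity draw succeeds, and the top of the study's dose
    grid reaches the chemical's potency; the LEL is then the smallest
    grid dose at or above the potency, and an inactive study reports the
    top grid dose as its HDT.  Compliance violations are planted after
    the outcome is fixed, so the ledger fully determines which records a
    GL filter must reject.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    designs = list(DESIGN_ORDER)
    weights = np.array([config.design_weights.get(d.label, 0.0) for d in designs],
                       dtype=float)
    if weights.sum() <= 0:
        raise ValueError("design_weights must have positive total mass")
    weights /= weights.sum()

    lo, hi = config.potency_log10_range
    grid = np.asarray(config.dose_grid, dtype=float)
    records: list[StudyRecord] = []
    rec_rows, chem_rows = [], []
    pub_counter = 0
    for ci in range(config.n_chemicals):
        casrn = make_casrn(100000 + ci)
        name = f"synthetic chemical {ci}"
        truly_active = bool(rng.random() < config.p_true_active)
        potency = float(10 ** rng.uniform(lo, hi))
        chem_rows.append({"casrn": casrn, "truly_active": truly_active,
                          "potency_mg_per_kg": potency})
        if isinstance(config.studies_per_chemical, int):
            n_studies = config.studies_per_chemical
        else:
            kind, p = config.studies_per_chemical
            if kind != "geometric":
                raise ValueError(f"unknown studies_per_chemical law {kind!r}")
            n_studies = int(rng.geometric(p))
        for si in range(n_studies):
            pub_counter += 1
            design = designs[int(rng.choice(len(designs), p=weights))]
            n_doses = int(rng.integers(2, config.max_doses_per_study + 1))
            start = int(rng.integers(0, len(grid) - n_doses + 1))
            doses = grid[start:start + n_doses]
            top = float(doses[-1])
            sens = config.design_sensitivity.get(design.label, 0.0)
            active = (truly_active and rng.random() < sens and top >= potency)
            if active:
                lel_value = float(doses[doses >= potency][0])
                lel = Dose(lel_value, MKD)
            else:
                lel = None
            rec_id = f"S{ci:05d}-{si:02d}"
            r = _compliant_record(
                record_id=rec_id,
                publication_id=f"PUB{pub_counter:06d}",
                casrn=casrn,
                name=name,
                design=design,
                outcome=Outcome.ACTIVE if active else Outcome.INACTIVE,
                lel=lel,
                highest_dose=Dose(top, MKD),
                n_dose_groups=n_doses,
            )
            planted = []
            for criterion, applies_to in ATOMIC_CRITERIA.items():
                rate = config.violation_rates.get(criterion, 0.0)
                if design.maturity not in applies_to:
                    continue
                if rate > 0 and rng.random() < rate:
                    _plant_violation(r, criterion, rng)
                    planted.append(criterion)
            records.append(r)
            rec_rows.append({"record_id": rec_id, "casrn": casrn,
                             "design": design.label,
                             "violations": ";".join(planted)})
    truth = GroundTruth(
        records=pd.DataFrame(rec_rows,
                             columns=["record_id", "casrn", "design", "violations"]),
        chemicals=pd.DataFrame(chem_rows,
                               columns=["casrn", "truly_active", "potency_mg_per_kg"]),
    )
    return records, truth


def fixture_from_design_counts(
    counts: dict[str, tuple[int, int]]
) -> list[StudyRecord]:
    """Minimal GL records realizing exact design-by-outcome counts.

    Each record gets its own synthetic chemical; the design summarizer
    inverts this builder exactly.
    """
    records: list[StudyRecord] = []
    i = 0
    for label, (n_active, n_inactive) in counts.items():
        if n_active < 0 or n_inactive < 0:
            raise ValueError(f"negative count for design {label!r}")
        design = DESIGN_BY_LABEL[label]
        for outcome, n in ((Outcome.ACTIVE, n_active), (Outcome.INACTIVE, n_inactive)):
            for _ in range(n):
                i += 1
                records.append(_compliant_record(
                    record_id=f"D{i:05d}",
                    publication_id=f"PUBD{i:05d}",
                    casrn=make_casrn(200000 + i),
                    name=f"design fixture chemical {i}",
                    design=design,
                    outcome=outcome,
                    lel=Dose(10.0, MKD) if outcome is Outcome.ACTIVE else None,
                    highest_dose=Dose(1000.0, MKD),
                ))
    return records


@dataclass
class ChemicalRow:
    """One per-chemical summary row to reconstruct studies from."""

    casrn: str
    name: str
    n_active: int
    n_inactive: int
    min_lel: Optional[float] = None
    max_hdt: Optional[float] = None
    lel_unit: DoseUnit = MKD
    active_designs: Optional[list[str]] = None   # labels, cycled over studies
    inactive_designs: Optional[list[str]] = None


def fixture_from_chemical_table(
    rows: Sequence[ChemicalRow], independent: bool = True
) -> list[StudyRecord]:
    """Reconstruct per-chemical study records from summary rows.

    One active record carries exactly ``min_lel`` and the rest carry ten
    times it; one inactive record carries exactly ``max_hdt`` and the
    rest a tenth of it — so aggregation recovers the row verbatim.  With
    ``independent=True`` every study gets a distinct publication id;
    otherwise all of a chemical's studies share one.
    """
    records: list[StudyRecord] = []
    for row in rows:
        a_designs = row.active_designs or ["Imm_Rat_Inj"]
        i_designs = row.inactive_designs or ["Imm_Rat_Inj"]
        for k in range(row.n_active):
            if row.min_lel is None:
                raise ValueError(f"{row.name}: active rows need min_lel")
            value = row.min_lel if k == 0 else row.min_lel * 10.0
            rid = f"{row.casrn}-A{k:02d}"
            pub = f"PUB-{row.casrn}-{k:02d}" if independent else f"PUB-{row.casrn}"
            records.append(_compliant_record(
                record_id=rid, publication_id=pub, casrn=row.casrn, name=row.name,
                design=DESIGN_BY_LABEL[a_designs[k % len(a_designs)]],
                outcome=Outcome.ACTIVE,
                lel=Dose(value, row.lel_unit),
                highest_dose=Dose(value * 10.0, row.lel_unit),
            ))
        for k in range(row.n_inactive):
            if row.max_hdt is None:
                raise ValueError(f"{row.name}: inactive rows need max_hdt")
            value = row.max_hdt if k == 0 else row.max_hdt / 10.0
            rid = f"{row.casrn}-I{k:02d}"
            pub = (f"PUB-{row.casrn}-{row.n_active + k:02d}" if independent
                   else f"PUB-{row.casrn}")
            records.append(_compliant_record(
                record_id=rid, publication_id=pub, casrn=row.casrn, name=row.name,
                design=DESIGN_BY_LABEL[i_designs[k % len(i_designs)]],
                outcome=Outcome.INACTIVE,
                lel=None,
                highest_dose=Dose(value, MKD),
            ))
    return records


# ---------------------------------------------------------------------------
# Packaged reference tables

def _data_path(name: str):
    return importlib.resources.files("uterodb.data").joinpath(name)


def load_design_counts() -> dict[str, tuple[int, int]]:
    """Published GL design-by-outcome counts (positive controls excluded)."""
    df = pd.read_csv(_data_path("design_outcome_counts.csv"))
    return {r.design: (int(r.n_active), int(r.n_inactive)) for r in df.itertuples()}


def _expand_designs(encoded: str, n: int, fallback: list[str]) -> list[str]:
    """Decode 'Label:count;Label:count' into a per-study design list."""
    if not encoded:
        return fallback
    out: list[str] = []
    for part in encoded.split(";"):
        label, count = part.split(":")
        out.extend([label] * int(count))
    if len(out) != n:
        raise ValueError(f"design breakdown {encoded!r} does not sum to {n}")
    return out


def load_discordant_rows() -> list[ChemicalRow]:
    """The 18 published discordant chemicals as reconstruction rows.

    Chemicals whose discordance the published analysis attributed to
    study-design differences get disjoint active (injection) and
    inactive (oral) designs; the rest keep both outcomes in the most
    common design.  The butylparaben row carries its published
    per-design outcome breakdown.
    """
    df = pd.read_csv(_data_path("discordant_chemicals.csv"), keep_default_na=False)
    rows = []
    for r in df.itertuples():
        differs = str(r.design_differs).lower() == "true"
        a_fb = ["Imm_Rat_Inj"]
        i_fb = ["Imm_Rat_Oral"] if differs else ["Imm_Rat_Inj"]
        rows.append(ChemicalRow(
            casrn=r.casrn, name=r.name,
            n_active=int(r.n_active), n_inactive=int(r.n_inactive),
            min_lel=float(r.min_lel), max_hdt=float(r.max_hdt),
            active_designs=_expand_designs(r.active_designs, int(r.n_active), a_fb),
            inactive_designs=_expand_designs(r.inactive_designs, int(r.n_inactive), i_fb),
        ))
    return rows


def load_reproducible_rows() -> list[ChemicalRow]:
    """The 36 published independently reproduced chemicals.

    Two chemicals report their minimum LEL only in mg per animal per
    day; their rows keep that unit so aggregation exercises the
    unit-fallback rule.
    """
    df = pd.read_csv(_data_path("reproducible_chemicals.csv"), keep_default_na=False)
    rows = []
    for r in df.itertuples():
        unit = (DoseUnit.MG_PER_ANIMAL_PER_DAY if "rat" in str(r.lel_unit)
                else MKD)
        rows.append(ChemicalRow(
            casrn=r.casrn, name=r.name,
            n_active=int(r.n_active), n_inactive=int(r.n_inactive),
            min_lel=float(r.min_lel) if str(r.min_lel) else None,
            max_hdt=float(r.max_hdt) if str(r.max_hdt) else None,
            lel_unit=unit,
        ))
    return rows
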