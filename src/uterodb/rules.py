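"""Guideline-like (GL) scoring of uterotrophic study protocols.

Six minimum criteria (MC1–MC6), each scored 0 or 1, determine whether a
study protocol is guideline-like, i.e. adherent to the protocol windows
of the regulatory uterotrophic test guidelines (OECD TG 440 / EPA OCSPP
890.1600) as relaxed for literature curation:

MC1  animal model    — immature rat, or OVX adult rat/mouse (immature
                       mice are excluded: potentially insensitive to
                       weak estrogens)
MC2  age / timing    — immature: dosing starts PND 18–21 and ends by
                       PND 25; OVX: surgery at 6–8 weeks of age with
                       ≥ 14 d (rat) / ≥ 7 d (mouse) recovery before dosing
MC3  group sizes     — ≥ 3 control animals and ≥ 5 per test group
MC4  route           — s.c., i.p. or oral gavage
MC5  dosing regimen  — ≥ 2 dose groups over ≥ 3 consecutive days
MC6  necropsy timing — 18–36 hr after the last dose

All windows are inclusive.  A criterion whose required fields are absent
scores 0 with ``missing_data`` set: compliance must be verifiable from
the record.  A protocol is GL iff all six criteria score 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .records import Route, Species, StudyRecord, StudyType

OVX_RECOVERY_DAYS = {Species.RAT: 14, Species.MOUSE: 7}
ACCEPTABLE_ROUTES = frozenset({Route.SC, Route.IP, Route.PO})


@dataclass(frozen=True)
class CriterionResult:
    criterion_id: str  # "MC1".."MC6"
    score: int         # 0 or 1
    reason: str
    missing_data: bool = False

    def __post_init__(self) -> None:
        if self.score not in (0, 1):
            raise ValueError(f"score must be 0 or 1, got {self.score}")
        if self.missing_data and self.score != 0:
            raise ValueError("missing data must score 0")


@dataclass(frozen=True)
class GLScore:
    record_id: str
    results: tuple[CriterionResult, ...]  # exactly six, MC1..MC6
    total: int
    is_gl: bool


def mc_animal_model(r: StudyRecord) -> CriterionResult:
    """MC1: immature rat or OVX adult rat/mouse."""
    if r.study_type is StudyType.IMMATURE:
        if r.species is Species.RAT:
            return CriterionResult("MC1", 1, "immature rat model")
        return CriterionResult("MC1", 0, "immature mouse excluded")
    if r.study_type is StudyType.OVX:
        if not r.is_adult:
            return CriterionResult("MC1", 0, "OVX model without confirmed adult status",
                                   missing_data=True)
        return CriterionResult("MC1", 1, f"OVX adult {r.species.value} model")
    return CriterionResult("MC1", 0, f"model '{r.study_type.value}' not acceptable")


def mc_age_timing(r: StudyRecord) -> CriterionResult:
    """MC2: immature PND window, or OVX surgery age + recovery time."""
    if r.study_type is StudyType.IMMATURE:
        if r.dose_start_pnd is None or r.dosing_length_days is None:
            return CriterionResult("MC2", 0, "immature dosing window not reported",
                                   missing_data=True)
        end = r.dose_start_pnd + r.dosing_length_days - 1
        if not 18 <= r.dose_start_pnd <= 21:
            return CriterionResult("MC2", 0,
                                   f"dosing starts PND {r.dose_start_pnd}, outside 18-21")
        if end > 25:
            return CriterionResult("MC2", 0, f"dosing ends PND {end}, after PND 25")
        return CriterionResult("MC2", 1, f"dosing PND {r.dose_start_pnd}-{end}")
    if r.study_type is StudyType.OVX:
        if r.ovx_age_weeks is None or r.days_post_ovx_before_dosing is None:
            return CriterionResult("MC2", 0, "OVX age or recovery time not reported",
                                   missing_data=True)
        if not 6 <= r.ovx_age_weeks <= 8:
            return CriterionResult("MC2", 0,
                                   f"OVX at {r.ovx_age_weeks} wk, outside 6-8 wk")
        need = OVX_RECOVERY_DAYS[r.species]
        if r.days_post_ovx_before_dosing < need:
            return CriterionResult(
                "MC2", 0,
                f"{r.days_post_ovx_before_dosing} d post-OVX, under the "
                f"{need} d minimum for {r.species.value}s")
        return CriterionResult("MC2", 1, f"OVX at {r.ovx_age_weeks} wk, "
                                         f"{r.days_post_ovx_before_dosing} d recovery")
    return CriterionResult("MC2", 0, "no timing window defined for this model")


def mc_group_size(r: StudyRecord) -> CriterionResult:
    """MC3: >= 3 control animals and >= 5 animals in every test group."""
    if r.n_control_animals is None or r.n_test_animals_min is None:
        return CriterionResult("MC3", 0, "group sizes not reported", missing_data=True)
    if r.n_control_animals < 3:
        return CriterionResult("MC3", 0, f"{r.n_control_animals} control animals < 3")
    if r.n_test_animals_min < 5:
        return CriterionResult("MC3", 0,
                               f"smallest test group {r.n_test_animals_min} < 5")
    return CriterionResult("MC3", 1, "group sizes adequate")


def mc_route(r: StudyRecord) -> CriterionResult:
    """MC4: s.c., i.p. or oral gavage."""
    if r.route in ACCEPTABLE_ROUTES:
        return CriterionResult("MC4", 1, f"route {r.route.value} acceptable")
    shown = r.route_original or r.route.value
    return CriterionResult("MC4", 0, f"route '{shown}' not acceptable")


def mc_dosing(r: StudyRecord) -> CriterionResult:
    """MC5: >= 2 dose groups over >= 3 consecutive days."""
    if r.dosing_length_days is None:
        return CriterionResult("MC5", 0, "dosing length not reported", missing_data=True)
    if r.n_dose_groups < 2:
        return CriterionResult("MC5", 0, f"{r.n_dose_groups} dose group(s) < 2")
    if r.dosing_length_days < 3 or not r.dosing_consecutive:
        return CriterionResult(
            "MC5", 0,
            f"{r.dosing_length_days} d"
            f"{'' if r.dosing_consecutive else ' non-consecutive'} dosing, "
            "under 3 consecutive days")
    return CriterionResult("MC5", 1, "dosing regimen adequate")


def mc_necropsy(r: StudyRecord) -> CriterionResult:
    """MC6: necropsy 18-36 hr after the last dose."""
    if r.necropsy_hr_after_last_dose is None:
        return CriterionResult("MC6", 0, "necropsy time not reported", missing_data=True)
    hr = r.necropsy_hr_after_last_dose
    if not 18 <= hr <= 36:
        return CriterionResult("MC6", 0, f"necropsy at {hr} hr, outside 18-36 hr")
    return CriterionResult("MC6", 1, f"necropsy at {hr} hr")


CRITERIA: tuple[Callable[[StudyRecord], CriterionResult], ...] = (
    mc_animal_model, mc_age_timing, mc_group_size, mc_route, mc_dosing, mc_necropsy,
)


def score_study(r: StudyRecord) -> GLScore:
    """Score all six criteria in fixed order; GL iff the total is 6."""
    results = tuple(fn(r) for fn in CRITERIA)
    total = sum(res.score for res in results)
    return GLScore(record_id=r.record_id, results=results, total=total,
                   is_gl=total == len(results))


def filter_gl(records: list[StudyRecord]) -> list[StudyRecord]:
    """Keep only guideline-like records, preserving input order."""
    return [r for r in records if score_study(r).is_gl]
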