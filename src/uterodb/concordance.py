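"""Design summaries and per-chemical concordance of uterotrophic outcomes.

Guideline-like study protocols fall into six design classes —
{immature rat, OVX rat, OVX mouse} × {injection, oral} — where
"injection" pools the s.c. and i.p. routes.  This module tabulates
outcomes by design, aggregates each chemical's evidence (active/inactive
counts, minimum LEL, maximum HDT), calls reproducibility, and, for
chemicals with both active and inactive GL outcomes, classifies the
discordance:

``dose_limited``
    every inactive study stopped below the lowest dose that produced an
    effect (maxHDT < minLEL): the results support rather than contradict
    one another.
``design_attributable``
    active and inactive outcomes come from disjoint sets of study
    designs (e.g. active by injection, inactive by oral gavage).
``same_design_conflict``
    at least one design class carries outcomes on both sides.

The precedence dose_limited > design_attributable > same_design_conflict
picks a single primary class; every applicable class is also kept as a
secondary flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .records import (
    Dose,
    DoseUnit,
    Outcome,
    Route,
    Species,
    StudyRecord,
    StudyType,
    UnitMismatchError,
    max_dose,
    min_dose,
)

log = logging.getLogger(__name__)

# CASRNs of the two steroids routinely run as positive controls; their
# results are excluded from design summaries (a failed positive control
# is rarely published, biasing their outcome distribution).
DEFAULT_CONTROL_CASRNS = frozenset({"57-63-6", "50-28-2"})

# Branched 4-nonylphenol: a mixture of branched chains, not one structure.
DEFAULT_MIXTURE_CASRNS = frozenset({"25154-52-3"})


@dataclass(frozen=True, order=True)
class StudyDesign:
    """One of the six GL design classes."""

    maturity: str      # "immature" | "ovx"
    species: Species
    route_class: str   # "injection" | "oral"

    @property
    def label(self) -> str:
        m = "Imm" if self.maturity == "immature" else "OVX"
        return f"{m}_{self.species.value.capitalize()}" \
               f"_{'Inj' if self.route_class == 'injection' else 'Oral'}"


DESIGN_ORDER: tuple[StudyDesign, ...] = (
    StudyDesign("immature", Species.RAT, "injection"),
    StudyDesign("immature", Species.RAT, "oral"),
    StudyDesign("ovx", Species.RAT, "injection"),
    StudyDesign("ovx", Species.RAT, "oral"),
    StudyDesign("ovx", Species.MOUSE, "injection"),
    StudyDesign("ovx", Species.MOUSE, "oral"),
)

DESIGN_BY_LABEL = {d.label: d for d in DESIGN_ORDER}


def design_key(r: StudyRecord) -> StudyDesign:
    """Map a GL record to its design class (s.c. and i.p. pool as injection)."""
    if r.route in (Route.SC, Route.IP):
        route_class = "injection"
    elif r.route is Route.PO:
        route_class = "oral"
    else:
        raise ValueError(
            f"record {r.record_id}: route {r.route.value!r} cannot occur in a GL record")
    maturity = "immature" if r.study_type is StudyType.IMMATURE else "ovx"
    return StudyDesign(maturity, r.species, route_class)


@dataclass
class DesignSummaryTable:
    """Outcome counts and fractions per study design.

    ``table`` is indexed by design label with columns n_active,
    n_inactive, pct_active, pct_inactive (fractions, 2 dp) and pct_total
    (percent of all summarized studies, 1 dp).
    """

    table: pd.DataFrame
    excluded_control_count: int

    def to_wide(self) -> pd.DataFrame:
        """Statistic rows x design columns, the conventional layout."""
        wide = self.table[["n_active", "n_inactive", "pct_active",
                           "pct_inactive", "pct_total"]].T
        wide.index = ["Number active", "Number inactive", "Percent active",
                      "Percent inactive", "Percent total"]
        return wide


def summarize_by_design(
    records: Sequence[StudyRecord],
    control_casrns: Iterable[str] = DEFAULT_CONTROL_CASRNS,
) -> DesignSummaryTable:
    """Tabulate GL outcomes by design, excluding positive-control substances."""
    control_casrns = set(control_casrns)
    kept = [r for r in records if r.casrn not in control_casrns]
    excluded = len(records) - len(kept)
    counts = {d: [0, 0] for d in DESIGN_ORDER}
    for r in kept:
        d = design_key(r)
        counts[d][0 if r.outcome is Outcome.ACTIVE else 1] += 1
    total = sum(a + i for a, i in counts.values())
    rows = []
    for d in DESIGN_ORDER:
        n_a, n_i = counts[d]
        n = n_a + n_i
        rows.append({
            "design": d.label,
            "n_active": n_a,
            "n_inactive": n_i,
            "pct_active": round(n_a / n, 2) if n else float("nan"),
            "pct_inactive": round(n_i / n, 2) if n else float("nan"),
            "pct_total": round(100.0 * n / total, 1) if total else float("nan"),
        })
    table = pd.DataFrame(rows).set_index("design")
    return DesignSummaryTable(table=table, excluded_control_count=excluded)


def headline_statistics(summary: DesignSummaryTable) -> dict[str, int]:
    """Whole-percent narrative statistics from a design summary.

    Returns percent-active across rat and mouse models, the immature-rat
    share of all studies, the injection share within immature-rat
    studies, and percent-active in the OVX mouse oral design.
    """
    t = summary.table
    n = t["n_active"] + t["n_inactive"]

    def pct(num: float, den: float) -> int:
        return round(100.0 * num / den)

    rat = [d.label for d in DESIGN_ORDER if d.species is Species.RAT]
    mouse = [d.label for d in DESIGN_ORDER if d.species is Species.MOUSE]
    imm = [d.label for d in DESIGN_ORDER if d.maturity == "immature"]
    return {
        "pct_active_rat_models": pct(t.loc[rat, "n_active"].sum(), n[rat].sum()),
        "pct_active_mouse_models": pct(t.loc[mouse, "n_active"].sum(), n[mouse].sum()),
        "pct_studies_immature_rat": pct(n[imm].sum(), n.sum()),
        "pct_injection_within_immature_rat": pct(n["Imm_Rat_Inj"], n[imm].sum()),
        "pct_active_ovx_mouse_oral": pct(t.loc["OVX_Mouse_Oral", "n_active"],
                                         n["OVX_Mouse_Oral"]),
    }


@dataclass
class ChemicalSummary:
    """Aggregated GL evidence and concordance call for one chemical."""

    casrn: str
    name: str
    n_gl_active: int = 0
    n_gl_inactive: int = 0
    min_lel: Optional[Dose] = None
    max_hdt: Optional[Dose] = None
    min_lel_unit_fallback: bool = False
    max_hdt_unit_fallback: bool = False
    n_publications_active: int = 0
    n_publications_total: int = 0
    call: str = ""
    discordance_class: str = "none"
    secondary_classes: tuple[str, ...] = ()
    flags: tuple[str, ...] = ()


def _extreme_with_fallback(doses: list[Dose], pick) -> tuple[Optional[Dose], bool, list[str]]:
    """Pick min/max preferring mg/kg/day; fall back to a single alternate unit."""
    flags: list[str] = []
    preferred = [d for d in doses if d.unit is DoseUnit.MG_PER_KG_PER_DAY]
    if preferred:
        return pick(preferred), False, flags
    if not doses:
        return None, False, flags
    try:
        return pick(doses), True, flags
    except UnitMismatchError:
        flags.append("unit_incomparable_extreme")
        return None, False, flags


def aggregate_chemical(records: Sequence[StudyRecord]) -> ChemicalSummary:
    """Aggregate one chemical's GL records into counts, minLEL and maxHDT.

    minLEL is taken over active studies reporting mg/kg/day; only when no
    active study reports that unit does it fall back to the minimum in
    the alternate unit (flagged).  maxHDT is treated symmetrically over
    inactive studies.
    """
    if not records:
        raise ValueError("aggregate_chemical requires at least one record")
    casrns = {r.casrn for r in records}
    if len(casrns) != 1:
        raise ValueError(f"records span multiple CASRNs: {sorted(casrns)}")
    actives = [r for r in records if r.outcome is Outcome.ACTIVE]
    inactives = [r for r in records if r.outcome is Outcome.INACTIVE]
    lels = [r.lel for r in actives if r.lel is not None]
    hdts = [r.highest_dose for r in inactives if r.highest_dose is not None]
    min_lel, lel_fb, f1 = _extreme_with_fallback(lels, min_dose)
    max_hdt, hdt_fb, f2 = _extreme_with_fallback(hdts, max_dose)
    return ChemicalSummary(
        casrn=records[0].casrn,
        name=records[0].chemical_name,
        n_gl_active=len(actives),
        n_gl_inactive=len(inactives),
        min_lel=min_lel,
        max_hdt=max_hdt,
        min_lel_unit_fallback=lel_fb,
        max_hdt_unit_fallback=hdt_fb,
        n_publications_active=len({r.publication_id for r in actives}),
        n_publications_total=len({r.publication_id for r in records}),
        flags=tuple(f1 + [f.replace("extreme", "hdt") for f in f2]),
    )


def concordance_call(s: ChemicalSummary, records: Sequence[StudyRecord]) -> ChemicalSummary:
    """Assign the reproducibility call.

    discordant: at least one active and one inactive GL study.  Otherwise
    concordant evidence from >= 2 studies counts as independently
    reproduced only when it spans >= 2 distinct publications; multiple
    protocols from a single publication are one laboratory's study.
    """
    n_a, n_i = s.n_gl_active, s.n_gl_inactive
    if n_a >= 1 and n_i >= 1:
        s.call = "discordant"
        return s
    side = "active" if n_a >= 1 else "inactive"
    n_side = n_a + n_i
    if n_side >= 2:
        if s.n_publications_total >= 2:
            s.call = f"reproducible_{side}"
        else:
            s.call = "not_independent"
    else:
        s.call = f"single_study_{side}"
    return s


DISCORDANCE_PRECEDENCE = ("dose_limited", "design_attributable", "same_design_conflict")


def classify_discordance(s: ChemicalSummary, records: Sequence[StudyRecord]) -> ChemicalSummary:
    """Classify why a discordant chemical's outcomes disagree.

    All applicable classes are retained; the primary class follows the
    precedence dose_limited > design_attributable > same_design_conflict
    (a dose-range explanation means the studies actually agree, so it
    outranks a design explanation).
    """
    if s.call != "discordant":
        s.discordance_class = "none"
        return s
    applicable: list[str] = []
    flags = list(s.flags)
    if s.min_lel is not None and s.max_hdt is not None:
        if s.min_lel.same_unit(s.max_hdt):
            if s.max_hdt.value < s.min_lel.value:
                applicable.append("dose_limited")
        else:
            flags.append("dose_limited_test_skipped_unit_mismatch")
    else:
        flags.append("dose_limited_test_skipped_missing_dose")
    active_designs = {design_key(r) for r in records if r.outcome is Outcome.ACTIVE}
    inactive_designs = {design_key(r) for r in records if r.outcome is Outcome.INACTIVE}
    if active_designs and inactive_designs and not (active_designs & inactive_designs):
        applicable.append("design_attributable")
    if not applicable:
        applicable.append("same_design_conflict")
    s.discordance_class = next(c for c in DISCORDANCE_PRECEDENCE if c in applicable)
    s.secondary_classes = tuple(c for c in applicable if c != s.discordance_class)
    s.flags = tuple(flags)
    return s


def apply_exclusions(
    records: Sequence[StudyRecord],
    mixture_casrns: Iterable[str] = DEFAULT_MIXTURE_CASRNS,
) -> list[StudyRecord]:
    """Drop records flagged as mixtures or whose CASRN is an excluded mixture."""
    mixture_casrns = set(mixture_casrns)
    kept, by_flag, by_casrn = [], 0, 0
    for r in records:
        if r.is_mixture:
            by_flag += 1
        elif r.casrn in mixture_casrns:
            by_casrn += 1
        else:
            kept.append(r)
    if by_flag or by_casrn:
        log.info("excluded %d records flagged as mixtures, %d by mixture CASRN list",
                 by_flag, by_casrn)
    return kept


def summarize_chemicals(records: Sequence[StudyRecord]) -> list[ChemicalSummary]:
    """Aggregate, call and classify every chemical in a set of GL records."""
    by_casrn: dict[str, list[StudyRecord]] = {}
    for r in records:
        by_casrn.setdefault(r.casrn, []).append(r)
    out = []
    for casrn in sorted(by_casrn):
        recs = by_casrn[casrn]
        s = aggregate_chemical(recs)
        s = concordance_call(s, recs)
        s = classify_discordance(s, recs)
        out.append(s)
    return out


def lel_hdt_profile(
    records: Sequence[StudyRecord], design: StudyDesign
) -> list[tuple[str, float, str]]:
    """Per-study dose anchors within one design, for dot-plot-style views.

    Returns (casrn, dose in mg/kg/day, outcome) with the LEL for active
    studies and the HDT for inactive ones; studies reporting other units
    are excluded with a logged count.
    """
    out: list[tuple[str, float, str]] = []
    skipped = 0
    for r in records:
        if design_key(r) != design:
            continue
        dose = r.lel if r.outcome is Outcome.ACTIVE else r.highest_dose
        if dose is None or dose.unit is not DoseUnit.MG_PER_KG_PER_DAY:
            skipped += 1
            continue
        out.append((r.casrn, dose.value, r.outcome.value))
    if skipped:
        log.info("profile for %s: skipped %d studies without mg/kg/day doses",
                 design.label, skipped)
    return out


def chemical_summary_frame(summaries: Sequence[ChemicalSummary]) -> pd.DataFrame:
    """Flatten chemical summaries into a DataFrame for reporting."""
    rows = []
    for s in summaries:
        rows.append({
            "casrn": s.casrn,
            "name": s.name,
            "n_gl_active": s.n_gl_active,
            "n_gl_inactive": s.n_gl_inactive,
            "min_lel_value": s.min_lel.value if s.min_lel else None,
            "min_lel_unit": s.min_lel.unit.value if s.min_lel else "",
            "max_hdt_value": s.max_hdt.value if s.max_hdt else None,
            "max_hdt_unit": s.max_hdt.unit.value if s.max_hdt else "",
            "min_lel_unit_fallback": s.min_lel_unit_fallback,
            "max_hdt_unit_fallback": s.max_hdt_unit_fallback,
            "n_publications_active": s.n_publications_active,
            "n_publications_total": s.n_publications_total,
            "call": s.call,
            "discordance_class": s.discordance_class,
            "secondary_classes": ";".join(s.secondary_classes),
            "flags": ";".join(s.flags),
        })
    return pd.DataFrame(rows)
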