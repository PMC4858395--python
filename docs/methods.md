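# Methods

## The curation model

`uterodb` treats literature curation of uterotrophic bioassays as a
deterministic pipeline over normalized study records:

    read → score six minimum criteria → keep guideline-like (GL) studies
    → drop mixture exclusions → design summary → per-chemical concordance

A *study record* is one chemical/study/protocol combination. Its
outcome is the curated binary call (active = significant uterine-weight
increase), anchored by the lowest effect level (LEL) for active studies
and the highest dose tested (HDT) for inactive ones. The pipeline never
re-derives outcomes from raw uterine weights; it curates reported
calls. A reported weight *decrease* is preserved in
`response_direction` but maps to `inactive` for ER-agonist
classification.

## Minimum criteria and their windows

Each criterion scores 0/1; GL requires all six. All windows are
inclusive and "at least" bounds are `>=`:

| criterion | rule | default interpretation choices |
|---|---|---|
| MC1 model | immature rat, or OVX adult rat/mouse | OVX without confirmed adult status fails with `missing_data` |
| MC2 timing | immature: start PND 18–21, end ≤ PND 25; OVX: surgery 6–8 wk, recovery ≥ 14 d (rat) / 7 d (mouse) | end day = start + length − 1 (day 1 is the first dosing day) |
| MC3 groups | controls ≥ 3, every test group ≥ 5 | `n_test_animals_min` stores the *minimum* treated-group size, since the rule binds on the smallest group |
| MC4 route | s.c. / i.p. / oral gavage | anything else (diet, drinking water …) fails |
| MC5 dosing | ≥ 2 dose groups, ≥ 3 consecutive days | single-dose studies fail |
| MC6 necropsy | 18–36 h after last dose | the literature phrase "1 day" is taken as exactly 24 h |

Missing required data fails the criterion (score 0, `missing_data`
flag): only studies whose compliance is verifiable from the record are
admitted. The exact partition of the textual requirements into six
criteria is a presentation choice; because GL demands *all* criteria,
any partition yields identical GL calls. The test suite verifies this
**grouping independence** against an oracle that evaluates the eleven
atomic predicates (model membership, immature start window, immature
completion bound, OVX age window, OVX recovery time, control size, test
size, route membership, dose-group count, dosing interval, necropsy
window) independently on randomized records.

## Dose units

Doses carry explicit units (`mg/kg/day`, `mg/animal/day`, `other`, with
the free-text original retained). Cross-unit comparison raises rather
than coercing; `normalize_dose` converts per-animal doses to mg/kg/day
only when a body weight is supplied, and is idempotent. CASRN check
digits are validated but only warn — the source tables are
authoritative even if a transcription were malformed.

## Design summary

The six design classes are {immature rat, OVX rat, OVX mouse} ×
{injection, oral}, where injection pools s.c. and i.p. Records for the
two routine positive-control substances (ethinyl estradiol 57-63-6,
estradiol 50-28-2; configurable) are excluded from design summaries:
failed positive controls are rarely published, biasing their outcome
distribution. Rounding follows the reporting conventions: within-design
fractions to 2 decimals, design shares to 1 decimal, narrative
percentages to whole percents.

## Per-chemical aggregation and concordance

For each chemical: `min_lel` is the minimum LEL over active studies
reporting mg/kg/day; only when *no* active study reports that unit does
it fall back to the minimum in the (single) alternate unit, flagged
`min_lel_unit_fallback`. If alternate-unit studies mix several units,
no extreme is reported and a flag records the refusal — cross-unit
minima are undefined. `max_hdt` over inactive studies is symmetric.

Calls: *discordant* iff ≥ 1 active and ≥ 1 inactive study; otherwise
≥ 2 concordant studies spanning ≥ 2 distinct publication identifiers →
*reproducible_active/_inactive*; ≥ 2 studies from one publication →
*not_independent* (multiple protocols in one paper are one laboratory's
study — publication identity operationalizes independence, since
laboratory is not a database field); else *single_study_\**.

Discordance classes, in precedence order:

1. `dose_limited` — maxHDT < minLEL in a shared unit; the inactive
   studies never reached an effective dose, so the results support one
   another. This outranks the design explanation for chemicals where
   both hold; the design class is kept as a secondary flag.
2. `design_attributable` — the design classes carrying active outcomes
   are disjoint from those carrying inactive ones.
3. `same_design_conflict` — some design class carries both.

If the two extremes are unit-incomparable the dose test is skipped and
flagged, never silently passed.

## Synthetic generator

`generate(SynthConfig)` emulates the statistical structure of a curated
study population:

* each chemical draws a latent activity (default `p_true_active = 0.6`,
  near the overall active fraction among GL outcomes) and a potency —
  the lowest effective dose — log-uniform over
  `potency_log10_range = (-5, 3)` mg/kg/day, since published
  minLEL/maxHDT values span more than seven orders of magnitude;
* studies per chemical follow a shifted geometric law (p = 0.45,
  mean ≈ 2.2) by default — the real distribution is highly skewed with
  most chemicals tested once or twice — or a fixed integer;
* each study draws a design (default frequencies proportional to the
  published design distribution), a contiguous window of ≤ 4 rungs from
  a decade-spaced master dose ladder, and is active iff the chemical is
  latently active, a design-sensitivity Bernoulli draw succeeds
  (defaults follow the published per-design active fractions), and the
  top dose reaches the potency. The LEL is the smallest tested dose at
  or above the potency; inactive studies report the top dose as HDT. A
  chemical whose potency exceeds every tested dose yields planted false
  negatives by construction;
* compliance violations are planted per atomic criterion at configured
  rates, each mutating one field strictly outside its window, and the
  ground-truth ledger lists every planted violation per record — so GL
  filtering must reject exactly the ledgered records (tested as an
  exact, all-seed property).

What the generator does **not** emulate: animal-level uterine-weight
variance and statistical testing (outcomes are curated calls, not raw
weights), correlated protocol choices within a publication, non-random
chemical selection across designs, and reporting bias. Passing tests
therefore demonstrate correctness of the curation logic, not fidelity
of any biological effect model.

Fixture builders complement the generator: `fixture_from_design_counts`
and `fixture_from_chemical_table` emit minimal GL-compliant record sets
that the summarizer/aggregator invert exactly, choosing canonical
in-window values (start PND 20, necropsy 24 h, controls 3 / test 6) for
fields the published rows do not constrain. The packaged reference
tables carry the published design-outcome counts (374 studies), the 18
discordant chemicals (with the published flag for design-attributable
discordance, and butylparaben's per-design outcome breakdown), and the
36 independently reproduced chemicals (with the per-animal LEL units of
mestranol and estriol preserved so aggregation exercises the unit
fallback). Non-discordant design placement for chemicals without a
published breakdown puts active studies in the most common design
(immature-rat injection) and, for design-attributable chemicals,
inactive studies in the oral variant — the constrained quantities
(counts, extremes, design disjointness) are exact; unconstrained filler
is canonical.

## Numerical and degenerate-input choices

* Rounding uses Python `round` at the printed precisions; no reported
  value sits on a half-way tie.
* Empty inputs produce empty tables and zero-count manifests, not
  errors; a design with no studies reports NaN fractions.
* Strict reading collects *all* schema violations (row and field) into
  one error; lenient reading coerces unknown vocabulary to `other` with
  a logged warning.
* Report CSVs have stable column order and byte-identical reruns.

## Problem sizes

The test suite and acceptance script run on the reconstructed fixtures
(374 and 353 records), 10,000 randomized records for the
grouping-independence oracle, and ~12,000 simulated studies
(≈ 2,000 per design) for sensitivity recovery within 3 binomial
standard errors; the whole suite completes in a few seconds.

## Known limitations

* No literature search, PDF/text mining, or two-reviewer
  reconciliation: inputs are already-transcribed protocol tables.
* No dose–response modeling; minLEL is a dose-grid-limited anchor, not
  a potency estimate.
* Quantitative response values (fold change, percent increase, log
  relative potency) are retained as free text only.
* Phytoestrogen-diet reporting is an informational flag, not a
  criterion; risk-of-bias and internal validity are out of scope.
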