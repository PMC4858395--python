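# uterodb

Curation and concordance analysis of rodent **uterotrophic bioassay**
study protocols.

The uterotrophic bioassay is the validated in vivo screen for estrogen
receptor (ER) agonists: a chemical is *active* when it causes a
statistically significant increase in uterine weight in immature or
ovariectomized (OVX) rodents. Published uterotrophic studies vary
widely in protocol quality, so literature-derived reference chemicals
for ER activity need a transparent, rule-based quality filter before
their outcomes can anchor in vitro or in silico methods. `uterodb` is a
library (plus a thin CLI) for toxicologists and cheminformaticians
doing exactly that curation:

1. **Score** each study protocol against six minimum criteria
   (MC1–MC6) derived from the regulatory test guidelines (OECD TG 440 /
   EPA OCSPP 890.1600), each 0/1:
   * MC1 animal model — immature rat or OVX adult rat/mouse
   * MC2 age/timing — immature dosing starts PND 18–21 and ends by
     PND 25; OVX at 6–8 weeks with ≥ 14 d (rat) / ≥ 7 d (mouse) recovery
   * MC3 group sizes — ≥ 3 controls, ≥ 5 per test group
   * MC4 route — s.c., i.p. or oral gavage
   * MC5 dosing — ≥ 2 dose groups over ≥ 3 consecutive days
   * MC6 necropsy — 18–36 h after the last dose

   A protocol is **guideline-like (GL)** iff all six criteria are met;
   missing required data conservatively fails a criterion.
2. **Summarize** GL outcomes over the six study designs
   {immature rat, OVX rat, OVX mouse} × {injection, oral}, with
   positive-control substances (ethinyl estradiol, estradiol) excluded.
3. **Aggregate** each chemical's evidence — active/inactive counts, the
   minimum lowest effect level (minLEL) and the maximum highest dose
   tested (maxHDT), preferring mg/kg/day units — and classify
   reproducibility: independently reproduced (≥ 2 concordant GL studies
   from ≥ 2 publications), not independent, single-study, or
   **discordant** (both active and inactive results). Discordance is
   explained as *dose-limited* (maxHDT < minLEL: the studies actually
   agree), *design-attributable* (active and inactive outcomes in
   disjoint designs), or a *same-design conflict*.
4. **Simulate** study populations with known ground truth — latent
   chemical potency, design-dependent sensitivity, log-spaced dose
   grids of ≤ 4 doses, and planted per-criterion compliance violations —
   so every pipeline stage is testable offline. Fixture builders
   reconstruct study sets from published summary rows exactly.

## Worked example

```python
import uterodb as u

records = u.fixture_from_design_counts(u.load_design_counts())  # 374 GL studies
summary = u.summarize_by_design(u.filter_gl(records))
print(summary.to_wide())
print(u.headline_statistics(summary))
```

prints

```
design            Imm_Rat_Inj  Imm_Rat_Oral  OVX_Rat_Inj  OVX_Rat_Oral  OVX_Mouse_Inj  OVX_Mouse_Oral
Number active          147.00         61.00        29.00           5.0          11.00            6.00
Number inactive         57.00         20.00         3.00           5.0          14.00           16.00
Percent active           0.72          0.75         0.91           0.5           0.44            0.27
Percent inactive         0.28          0.25         0.09           0.5           0.56            0.73
Percent total           54.50         21.70         8.60           2.7           6.70            5.90

{'pct_active_rat_models': 74, 'pct_active_mouse_models': 36,
 'pct_studies_immature_rat': 76, 'pct_injection_within_immature_rat': 72,
 'pct_active_ovx_mouse_oral': 27}
```

Per design: the active/inactive study counts, the within-design active
fraction, and the design's share of all GL studies. Rat models report
active outcomes far more often (74%) than mouse models (36%), and
injection more often than oral gavage — the key protocol effects a user
of uterotrophic reference data must account for.

Per-chemical concordance on the 54 published multi-study chemicals:

```python
rows = u.load_discordant_rows() + u.load_reproducible_rows()
summaries = u.summarize_chemicals(u.fixture_from_chemical_table(rows))
# -> 18 discordant, 24 reproducible_active, 12 reproducible_inactive;
#    butylparaben: design_attributable, bisphenol A: same_design_conflict,
#    benzophenone/permethrin/daidzein: dose_limited
```

The `examples/` directory has one short narrative script per
capability; the `uterodb` command exposes the same stages as
subcommands (`validate`, `summarize`, `concordance`, `simulate`,
`run`).

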