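"""Per-chemical reproducibility calls and discordance classes.

Rebuilds study records for the 54 published multi-study chemicals (18
discordant + 36 independently reproduced), aggregates each chemical's
evidence (counts, minimum LEL, maximum HDT), and classifies concordance.
A discordant chemical has at least one active and one inactive GL study;
its discordance is dose-limited (inactive studies stopped below the
lowest effective dose), design-attributable (active and inactive
outcomes in disjoint design classes), or a same-design conflict.
"""

from collections import Counter

import uterodb as u

rows = u.load_discordant_rows() + u.load_reproducible_rows()
records = u.fixture_from_chemical_table(rows, independent=True)
summaries = u.summarize_chemicals(u.filter_gl(records))

print("concordance calls:", dict(Counter(s.call for s in summaries)))
print("discordance classes:",
      dict(Counter(s.discordance_class for s in summaries
                   if s.call == "discordant")))
print()
for name in ("Butylparaben", "Bisphenol A", "Benzophenone", "Mestranol"):
    s = next(x for x in summaries if x.name == name)
    lel = f"{s.min_lel.value} {s.min_lel.unit.value}" if s.min_lel else "-"
    hdt = f"{s.max_hdt.value} {s.max_hdt.unit.value}" if s.max_hdt else "-"
    print(f"{name}: {s.n_gl_active} active / {s.n_gl_inactive} inactive, "
          f"minLEL {lel}, maxHDT {hdt}, call={s.call}, "
          f"class={s.discordance_class}")

# Butylparaben is active in every injection design and inactive in every
# oral one (design-attributable); bisphenol A is both active and
# inactive within the immature-rat injection design (same-design
# conflict); benzophenone's inactive studies never reached its lowest
# effective dose (dose-limited); mestranol's minimum LEL is reported
# only per animal, so the unit-fallback flag is set on its summary.
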