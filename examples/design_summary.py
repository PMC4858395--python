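"""Tabulate guideline-like outcomes by study design.

Reconstructs the 374 GL study records realizing the published
design-by-outcome counts (positive-control substances already excluded)
and prints the per-design summary: active/inactive counts, the active
fraction within each design, and each design's share of all studies.
Injection designs — especially in rats — report active outcomes far more
often than oral-gavage designs.
"""

import uterodb as u

records = u.fixture_from_design_counts(u.load_design_counts())
summary = u.summarize_by_design(u.filter_gl(records))

print(summary.to_wide().to_string())
print()
for key, value in u.headline_statistics(summary).items():
    print(f"{key}: {value}%")

# pct_active is the fraction of studies in that design reporting a
# significant uterine-weight increase; pct_total is the design's share
# of all 374 summarized GL studies.
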