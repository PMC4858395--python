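"""Score individual study protocols against the six minimum criteria.

Builds two study records — a guideline-compliant immature-rat injection
study and an immature-mouse variant — and prints their criterion-level
verdicts.  A study is guideline-like (GL) only when all six criteria
score 1; the mouse study fails MC1 because immature mice may be
insensitive to weak estrogens.
"""

import uterodb as u

rat = u.StudyRecord(
    record_id="demo-rat", publication_id="12345", casrn="94-26-8",
    chemical_name="Butylparaben", species=u.Species.RAT,
    study_type=u.StudyType.IMMATURE, route=u.Route.SC,
    dose_start_pnd=20, dosing_length_days=3, dosing_consecutive=True,
    n_dose_groups=3, n_control_animals=3, n_test_animals_min=6,
    necropsy_hr_after_last_dose=24.0, outcome=u.Outcome.ACTIVE,
    lel=u.Dose(50.0, u.DoseUnit.MG_PER_KG_PER_DAY),
    highest_dose=u.Dose(500.0, u.DoseUnit.MG_PER_KG_PER_DAY),
)
import dataclasses
mouse = dataclasses.replace(rat, record_id="demo-mouse", species=u.Species.MOUSE)

for record in (rat, mouse):
    score = u.score_study(record)
    print(f"\n{record.record_id}: total {score.total}/6, GL={score.is_gl}")
    for res in score.results:
        print(f"  {res.criterion_id} = {res.score}  ({res.reason})")

# The criterion verdicts are data, not errors: a 5/6 protocol is simply
# excluded from the GL subset downstream.
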