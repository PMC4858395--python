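import numpy as np
import pytest

import uterodb as u


@pytest.fixture(scope="session")
def design_count_records():
    """374 GL records realizing the published design-by-outcome counts."""
    return u.fixture_from_design_counts(u.load_design_counts())


@pytest.fixture(scope="session")
def chemical_table_records():
    """Per-chemical records rebuilt from the published discordant and
    independently-reproduced chemical rows, with distinct publications."""
    rows = u.load_discordant_rows() + u.load_reproducible_rows()
    return u.fixture_from_chemical_table(rows, independent=True)


@pytest.fixture(scope="session")
def chemical_summaries(chemical_table_records):
    return u.summarize_chemicals(chemical_table_records)


def compliant_record(**overrides):
    """A fully GL-compliant immature-rat injection study to perturb."""
    base = dict(
        record_id="R1",
        publication_id="P1",
        casrn="80-05-7",
        chemical_name="Bisphenol A",
        species=u.Species.RAT,
        study_type=u.StudyType.IMMATURE,
        route=u.Route.SC,
        dose_start_pnd=20,
        is_adult=False,
        dosing_length_days=3,
        dosing_consecutive=True,
        n_dose_groups=3,
        highest_dose=u.Dose(1000.0, u.DoseUnit.MG_PER_KG_PER_DAY),
        n_control_animals=3,
        n_test_animals_min=6,
        necropsy_hr_after_last_dose=24.0,
        outcome=u.Outcome.ACTIVE,
        lel=u.Dose(10.0, u.DoseUnit.MG_PER_KG_PER_DAY),
    )
    base.update(overrides)
    return u.StudyRecord(**base)


def compliant_ovx_record(species=u.Species.RAT, **overrides):
    base = dict(
        study_type=u.StudyType.OVX,
        species=species,
        is_adult=True,
        dose_start_pnd=None,
        ovx_age_weeks=7.0,
        days_post_ovx_before_dosing=14,
    )
    base.update(overrides)
    return compliant_record(**base)


def random_records(n, seed):
    """Records with every criterion field drawn from in- and out-of-window
    values (including absences), for oracle comparisons."""
    rng = np.random.default_rng(seed)
    mkd = u.DoseUnit.MG_PER_KG_PER_DAY

    def pick(options, p=None):
        return options[int(rng.choice(len(options), p=p))]

    out = []
    for i in range(n):
        study_type = pick([u.StudyType.IMMATURE, u.StudyType.OVX,
                           u.StudyType.INTACT, u.StudyType.OTHER],
                          p=[0.4, 0.4, 0.1, 0.1])
        immature = study_type == u.StudyType.IMMATURE
        rec = u.StudyRecord(
            record_id=f"RND{i}",
            publication_id=f"P{i}",
            casrn="80-05-7",
            chemical_name="x",
            species=pick([u.Species.RAT, u.Species.MOUSE]),
            study_type=study_type,
            route=pick([u.Route.SC, u.Route.IP, u.Route.PO, u.Route.OTHER]),
            dose_start_pnd=pick([None, 16, 18, 20, 21, 22, 26]) if immature else None,
            is_adult=bool(rng.random() < 0.7),
            ovx_age_weeks=(None if immature
                           else pick([None, 4.0, 6.0, 7.0, 8.0, 10.0])),
            days_post_ovx_before_dosing=(None if immature
                                         else pick([None, 0, 6, 7, 13, 14, 30])),
            dosing_length_days=pick([None, 1, 2, 3, 4, 6, 9]),
            dosing_consecutive=bool(rng.random() < 0.8),
            n_dose_groups=int(rng.integers(0, 5)),
            highest_dose=u.Dose(1000.0, mkd),
            n_control_animals=pick([None, 0, 2, 3, 6]),
            n_test_animals_min=pick([None, 1, 4, 5, 8]),
            necropsy_hr_after_last_dose=pick([None, 6.0, 18.0, 24.0, 36.0, 48.0]),
            outcome=u.Outcome.INACTIVE,
        )
        out.append(rec)
    return out


def atomic_predicates(r):
    """Independent atomic compliance predicates (the brute-force oracle).

    Model-specific window predicates are vacuously true for models they
    do not apply to; absence of a required field fails its predicate.
    """
    immature = r.study_type == u.StudyType.IMMATURE
    ovx = r.study_type == u.StudyType.OVX
    model_ok = (immature and r.species == u.Species.RAT) or (ovx and r.is_adult)
    imm_start = (not immature) or (r.dose_start_pnd is not None
                                   and 18 <= r.dose_start_pnd <= 21)
    imm_end = (not immature) or (r.dose_start_pnd is not None
                                 and r.dosing_length_days is not None
                                 and r.dose_start_pnd + r.dosing_length_days - 1 <= 25)
    ovx_age = (not ovx) or (r.ovx_age_weeks is not None and 6 <= r.ovx_age_weeks <= 8)
    need = 14 if r.species == u.Species.RAT else 7
    ovx_rec = (not ovx) or (r.days_post_ovx_before_dosing is not None
                            and r.days_post_ovx_before_dosing >= need)
    ctrl = r.n_control_animals is not None and r.n_control_animals >= 3
    test = r.n_test_animals_min is not None and r.n_test_animals_min >= 5
    route = r.route in (u.Route.SC, u.Route.IP, u.Route.PO)
    groups = r.n_dose_groups >= 2
    interval = (r.dosing_length_days is not None and r.dosing_length_days >= 3
                and r.dosing_consecutive)
    necropsy = (r.necropsy_hr_after_last_dose is not None
                and 18 <= r.necropsy_hr_after_last_dose <= 36)
    window_defined = immature or ovx
    return [model_ok and window_defined, imm_start, imm_end, ovx_age, ovx_rec,
            ctrl, test, route, groups, interval, necropsy]
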