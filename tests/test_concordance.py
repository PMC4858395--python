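"""Design keys, design summaries, chemical aggregation and discordance."""

import pytest

import uterodb as u

from conftest import compliant_ovx_record, compliant_record

MKD = u.DoseUnit.MG_PER_KG_PER_DAY
MAD = u.DoseUnit.MG_PER_ANIMAL_PER_DAY


class TestDesignKey:
    def test_immature_rat_sc_is_injection(self):
        assert u.design_key(compliant_record()).label == "Imm_Rat_Inj"

    def test_ip_pools_with_sc_as_injection(self):
        r = compliant_ovx_record(species=u.Species.MOUSE, route=u.Route.IP,
                                 days_post_ovx_before_dosing=7)
        assert u.design_key(r).label == "OVX_Mouse_Inj"

    def test_oral_gavage_maps_to_oral(self):
        assert u.design_key(compliant_ovx_record(route=u.Route.PO)
                            ).label == "OVX_Rat_Oral"

    def test_other_route_is_internal_inconsistency(self):
        with pytest.raises(ValueError):
            u.design_key(compliant_record(route=u.Route.OTHER))


class TestDesignSummary:
    def test_reproduces_published_fractions(self, design_count_records):
        s = u.summarize_by_design(design_count_records)
        assert list(s.table["pct_active"]) == [0.72, 0.75, 0.91, 0.50, 0.44, 0.27]
        assert list(s.table["pct_total"]) == [54.5, 21.7, 8.6, 2.7, 6.7, 5.9]

    def test_fraction_rows_sum_to_one_and_totals_to_hundred(self, design_count_records):
        s = u.summarize_by_design(design_count_records)
        assert ((s.table["pct_active"] + s.table["pct_inactive"] - 1).abs()
                <= 0.01).all()
        assert abs(s.table["pct_total"].sum() - 100.0) <= 0.3

    def test_counts_conserved_with_control_exclusion(self, design_count_records):
        controls = [compliant_record(record_id=f"C{i}", casrn="57-63-6",
                                     chemical_name="Ethinyl Estradiol")
                    for i in range(5)]
        s = u.summarize_by_design(design_count_records + controls)
        assert s.excluded_control_count == 5
        n = (s.table["n_active"] + s.table["n_inactive"]).sum()
        assert n + s.excluded_control_count == len(design_count_records) + 5

    def test_single_record_design(self):
        s = u.summarize_by_design([compliant_record()])
        assert s.table.loc["Imm_Rat_Inj", "pct_active"] == 1.00
        assert s.table.loc["Imm_Rat_Inj", "pct_total"] == 100.0

    def test_empty_after_exclusion_is_empty_table(self):
        controls = [compliant_record(casrn="57-63-6")]
        s = u.summarize_by_design(controls)
        assert (s.table[["n_active", "n_inactive"]].sum().sum()) == 0

    def test_headline_statistics(self, design_count_records):
        stats = u.headline_statistics(u.summarize_by_design(design_count_records))
        assert stats == {
            "pct_active_rat_models": 74,
            "pct_active_mouse_models": 36,
            "pct_studies_immature_rat": 76,
            "pct_injection_within_immature_rat": 72,
            "pct_active_ovx_mouse_oral": 27,
        }


def records_for(name, summaries_records):
    return [r for r in summaries_records if r.chemical_name == name]


def summary_for(name, summaries):
    return next(s for s in summaries if s.name == name)


class TestAggregateChemical:
    def test_butylparaben_counts_and_extremes(self, chemical_table_records):
        recs = records_for("Butylparaben", chemical_table_records)
        s = u.aggregate_chemical(recs)
        assert (s.n_gl_active, s.n_gl_inactive) == (8, 2)
        assert s.min_lel.value == 50 and s.min_lel.unit is MKD
        assert s.max_hdt.value == 1000

    def test_estradiol_all_active(self, chemical_table_records):
        s = u.aggregate_chemical(records_for("Estradiol", chemical_table_records))
        assert (s.n_gl_active, s.n_gl_inactive) == (25, 0)
        assert s.min_lel.value == pytest.approx(1e-5)
        assert s.max_hdt is None

    def test_mestranol_alternate_unit_fallback(self, chemical_table_records):
        s = u.aggregate_chemical(records_for("Mestranol", chemical_table_records))
        assert s.min_lel_unit_fallback
        assert s.min_lel.unit is MAD
        assert s.min_lel.value == pytest.approx(8e-5)

    def test_mg_per_kg_preferred_over_lower_alternate_unit(self):
        recs = [compliant_record(record_id="a", lel=u.Dose(10.0, MKD)),
                compliant_record(record_id="b", lel=u.Dose(0.5, MAD),
                                 highest_dose=u.Dose(5.0, MAD))]
        s = u.aggregate_chemical(recs)
        assert s.min_lel.unit is MKD and s.min_lel.value == 10.0
        assert not s.min_lel_unit_fallback

    def test_multiple_casrns_refused(self):
        recs = [compliant_record(), compliant_record(casrn="446-72-0")]
        with pytest.raises(ValueError):
            u.aggregate_chemical(recs)

    def test_min_lel_monotone_under_added_actives(self):
        recs = [compliant_record(record_id="a", lel=u.Dose(100.0, MKD))]
        s1 = u.aggregate_chemical(recs)
        recs.append(compliant_record(record_id="b", lel=u.Dose(10.0, MKD)))
        s2 = u.aggregate_chemical(recs)
        assert s2.min_lel.value <= s1.min_lel.value


class TestConcordanceCall:
    def test_genistein_discordant(self, chemical_summaries):
        assert summary_for("Genistein", chemical_summaries).call == "discordant"

    def test_diethyl_phthalate_reproducible_inactive(self, chemical_summaries):
        assert summary_for("Diethyl phthalate",
                           chemical_summaries).call == "reproducible_inactive"

    def test_two_actives_from_one_publication_not_independent(self):
        rows = [u.ChemicalRow(casrn="80-05-7", name="x", n_active=2,
                              n_inactive=0, min_lel=1.0)]
        recs = u.fixture_from_chemical_table(rows, independent=False)
        (s,) = u.summarize_chemicals(recs)
        assert s.call == "not_independent"

    def test_single_study_calls(self):
        rows = [u.ChemicalRow(casrn="80-05-7", name="x", n_active=1,
                              n_inactive=0, min_lel=1.0)]
        (s,) = u.summarize_chemicals(u.fixture_from_chemical_table(rows))
        assert s.call == "single_study_active"

    def test_call_counts_on_reference_fixture(self, chemical_summaries):
        calls = [s.call for s in chemical_summaries]
        assert calls.count("discordant") == 18
        assert calls.count("reproducible_active") == 24
        assert calls.count("reproducible_inactive") == 12


class TestClassifyDiscordance:
    def test_dose_limited_chemicals_exactly(self, chemical_summaries):
        dose_limited = {s.name for s in chemical_summaries
                        if s.call == "discordant"
                        and s.max_hdt.value < s.min_lel.value}
        assert dose_limited == {"Benzophenone", "Permethrin", "Daidzein"}
        for s in chemical_summaries:
            if s.name in dose_limited:
                assert s.discordance_class == "dose_limited"

    def test_butylparaben_design_attributable(self, chemical_summaries):
        assert summary_for("Butylparaben",
                           chemical_summaries).discordance_class == "design_attributable"

    def test_bisphenol_a_same_design_conflict(self, chemical_summaries):
        assert summary_for("Bisphenol A",
                           chemical_summaries).discordance_class == "same_design_conflict"

    def test_precedence_keeps_secondary_classes(self, chemical_summaries):
        perm = summary_for("Permethrin", chemical_summaries)
        assert perm.discordance_class == "dose_limited"
        assert "design_attributable" in perm.secondary_classes

    def test_every_discordant_chemical_has_one_primary_class(self, chemical_summaries):
        for s in chemical_summaries:
            if s.call == "discordant":
                assert s.discordance_class in ("dose_limited", "design_attributable",
                                               "same_design_conflict")
            else:
                assert s.discordance_class == "none"

    def test_unit_incomparable_extremes_skip_dose_test(self):
        recs = [compliant_record(record_id="a", lel=u.Dose(5.0, MAD),
                                 highest_dose=u.Dose(50.0, MAD)),
                compliant_record(record_id="b", outcome=u.Outcome.INACTIVE,
                                 lel=None, route=u.Route.PO)]
        (s,) = u.summarize_chemicals(recs)
        assert s.call == "discordant"
        assert any("unit_mismatch" in f for f in s.flags)
        assert s.discordance_class == "design_attributable"


class TestConservationAndProfiles:
    def test_chemical_counts_conserve_records(self, chemical_table_records):
        summaries = u.summarize_chemicals(chemical_table_records)
        total = sum(s.n_gl_active + s.n_gl_inactive for s in summaries)
        assert total == len(chemical_table_records)

    def test_bpa_profile_in_immature_rat_injection(self, chemical_table_records):
        design = u.DESIGN_ORDER[0]
        profile = u.lel_hdt_profile(chemical_table_records, design)
        assert ("80-05-7", 2.0, "active") in profile
        assert ("80-05-7", 1000.0, "inactive") in profile

    def test_profile_of_empty_design_is_empty(self):
        records = [compliant_record()]  # injection only
        oral = u.DESIGN_ORDER[1]
        assert u.lel_hdt_profile(records, oral) == []

    def test_profile_matches_brute_force_filter(self, chemical_table_records):
        design = u.DESIGN_ORDER[0]
        profile = u.lel_hdt_profile(chemical_table_records, design)
        expected = []
        for r in chemical_table_records:
            if u.design_key(r) != design:
                continue
            d = r.lel if r.outcome is u.Outcome.ACTIVE else r.highest_dose
            if d is not None and d.unit is MKD:
                expected.append((r.casrn, d.value, r.outcome.value))
        assert profile == expected


class TestExclusions:
    def test_mixture_casrn_excluded(self):
        mix = [compliant_record(record_id=f"M{i}", casrn="25154-52-3",
                                chemical_name="4-Nonylphenol (branched)")
               for i in range(3)]
        keep = [compliant_record(record_id="K")]
        out = u.apply_exclusions(keep + mix)
        assert out == keep

    def test_is_mixture_flag_excluded(self):
        r = compliant_record(is_mixture=True)
        assert u.apply_exclusions([r]) == []

    def test_empty_exclusion_list_is_identity(self):
        records = [compliant_record(record_id=f"R{i}") for i in range(4)]
        assert u.apply_exclusions(records, mixture_casrns=()) == records
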