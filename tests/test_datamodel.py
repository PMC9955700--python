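"""Cohort I/O, body-map regions, case definitions, and scale scoring."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinpain.datamodel import (
    SITES,
    IntegrityError,
    IndividualRecord,
    MappingError,
    Role,
    ScaleError,
    SchemaError,
    Tristate,
    Zygosity,
    classify_back_pain,
    classify_condition,
    map_sites_to_regions,
    read_cohort,
    score_scale,
)


class TestReadCohort:
    def test_toy_file_loads_four_records_one_family(self, toy_cohort_csv):
        cohort = read_cohort(toy_cohort_csv)
        assert len(cohort) == 4
        assert cohort.family_ids == ["F1"]
        twin1 = cohort.by_role(Role.TWIN1)[0]
        assert twin1.zygosity is Zygosity.MZ
        assert twin1.lbp_life is Tristate.CASE
        assert twin1.pain_sites == {"neck", "lower_back"}
        father = cohort.by_role(Role.FATHER)[0]
        assert father.lbp_life is Tristate.MISSING

    def test_yes_no_na_dialect(self, tmp_path):
        path = tmp_path / "dialect.csv"
        path.write_text(
            "family_id,role,zygosity,age,sex,lbp_life,tlbp_current\n"
            "F1,twin1,DZ,12,male,yes,no\n"
            "F1,twin2,DZ,12,male,NA,yes\n"
        )
        dialect = {"yes": Tristate.CASE, "no": Tristate.CONTROL,
                   "NA": Tristate.MISSING}
        cohort = read_cohort(path, dialect=dialect)
        t1, t2 = cohort.records
        assert t1.lbp_life is Tristate.CASE
        assert t1.tlbp_current is Tristate.CONTROL
        assert t2.lbp_life is Tristate.MISSING

    def test_missing_mandatory_column_names_it(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("family_id,role,zygosity,age,sex,lbp_life\nF1,twin1,MZ,9,male,1\n")
        with pytest.raises(SchemaError, match="tlbp_current"):
            read_cohort(path)

    def test_duplicate_twin_is_integrity_error(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "family_id,role,zygosity,age,sex,lbp_life,tlbp_current\n"
            "F1,twin1,MZ,9,male,1,0\n"
            "F1,twin1,MZ,9,male,0,0\n"
        )
        with pytest.raises(IntegrityError, match="F1"):
            read_cohort(path)

    def test_most_important_site_outside_sites_warns_not_fails(self, tmp_path):
        path = tmp_path / "warn.csv"
        path.write_text(
            "family_id,role,zygosity,age,sex,pain_sites,most_important_site,"
            "lbp_life,tlbp_current\n"
            "F1,twin1,MZ,9,male,neck,head,0,0\n"
        )
        cohort = read_cohort(path)
        assert len(cohort) == 1
        assert len(cohort.warnings) == 1
        assert "head" in cohort.warnings[0]


class TestRegions:
    def test_lower_limb_sites_map_to_lower_limbs_only(self):
        profile = map_sites_to_regions({"shins", "thighs"})
        assert profile["lower_limbs"]
        assert profile.positive_regions() == {"lower_limbs"}

    def test_empty_set_gives_all_false(self):
        profile = map_sites_to_regions(set())
        assert profile.positive_regions() == frozenset()
        assert not profile.tlbp_region

    def test_middle_back_triggers_tlbp_region(self):
        assert map_sites_to_regions({"middle_back"}).tlbp_region
        assert map_sites_to_regions({"lower_back"}).tlbp_region
        assert not map_sites_to_regions({"upper_back"}).tlbp_region

    def test_unknown_site_names_the_code(self):
        with pytest.raises(MappingError, match="eyebrow"):
            map_sites_to_regions({"eyebrow"})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.sets(st.sampled_from(SITES)), st.sets(st.sampled_from(SITES)))
    def test_order_invariant_and_idempotent_under_union(self, s1, s2):
        p1 = map_sites_to_regions(s1)
        assert map_sites_to_regions(sorted(s1)) == p1
        p_union = map_sites_to_regions(s1 | s2)
        assert p_union.positive_regions() == (
            p1.positive_regions() | map_sites_to_regions(s2).positive_regions()
        )
        # re-mapping the union with its own sites changes nothing
        assert map_sites_to_regions((s1 | s2) | s1) == p_union

    def test_multiple_sites_excludes_index_regions(self):
        profile = map_sites_to_regions({"lower_back", "neck", "knees"})
        assert profile.multiple_sites(exclude=("lower_back",))
        assert not map_sites_to_regions({"lower_back", "neck"}).multiple_sites(
            exclude=("lower_back",)
        )


def _record(**kw):
    base = dict(family_id="F1", role=Role.TWIN1, zygosity=Zygosity.MZ, age=12.0)
    base.update(kw)
    return IndividualRecord(**base)


class TestBackPainClassifier:
    def test_minor_injury_does_not_exclude(self):
        r = _record(lbp_life=Tristate.CASE, injury_flag=Tristate.CASE,
                    serious_injury_or_disease=Tristate.CONTROL)
        st = classify_back_pain(r)
        assert st.lbp_life is Tristate.CASE
        assert not st.lbp_excluded

    def test_serious_disease_excludes_and_flags(self):
        r = _record(lbp_life=Tristate.CASE, serious_injury_or_disease=Tristate.CASE)
        st = classify_back_pain(r)
        assert st.lbp_life is not Tristate.CASE
        assert st.lbp_excluded

    def test_head_only_current_pain_is_tlbp_control(self):
        r = _record(tlbp_current=Tristate.CASE, pain_sites=frozenset({"head"}))
        assert classify_back_pain(r).tlbp_current is Tristate.CONTROL

    def test_back_site_current_pain_is_tlbp_case(self):
        r = _record(tlbp_current=Tristate.CASE,
                    pain_sites=frozenset({"middle_back"}))
        assert classify_back_pain(r).tlbp_current is Tristate.CASE

    def test_missing_propagates(self):
        st = classify_back_pain(_record())
        assert st.lbp_life is Tristate.MISSING
        assert st.tlbp_current is Tristate.MISSING

    def test_never_case_when_serious(self):
        for lbp in Tristate:
            r = _record(lbp_life=lbp, tlbp_current=lbp,
                        pain_sites=frozenset({"lower_back"}) if lbp is Tristate.CASE
                        else frozenset(),
                        serious_injury_or_disease=Tristate.CASE)
            st = classify_back_pain(r)
            assert st.lbp_life is not Tristate.CASE
            assert st.tlbp_current is not Tristate.CASE


MIGRAINE_FULL = dict(
    attacks_at_least_5=True, duration_4_to_72h=True, unilateral=True,
    pulsating=True, moderate_or_severe=False, aggravated_by_activity=False,
    nausea_or_vomiting=True, photophobia_and_phonophobia=False,
    recurring_headaches=True,
)
GP_FULL = dict(
    bilateral_lower_limb_pain=True, onset_age=7, night_pain=True,
    no_significant_limitation=True, orthopedic_disorder=False,
    abnormal_tests=False,
)


class TestConditionClassifiers:
    def test_migraine_needs_two_of_four_features(self):
        items = dict(MIGRAINE_FULL)
        assert classify_condition(None, "migraine", items) is Tristate.CASE
        items["pulsating"] = False  # only one feature left
        assert classify_condition(None, "migraine", items) is Tristate.CONTROL

    def test_headache_only_when_migraine_criteria_fail(self):
        items = dict(MIGRAINE_FULL)
        assert classify_condition(None, "headache", items) is Tristate.CONTROL
        items["pulsating"] = False
        assert classify_condition(None, "headache", items) is Tristate.CASE

    def test_growing_pains_onset_window(self):
        assert classify_condition(None, "growing_pains", GP_FULL) is Tristate.CASE
        late = dict(GP_FULL, onset_age=14)
        assert classify_condition(None, "growing_pains", late) is Tristate.CONTROL

    def test_growing_pains_exclusion_criteria(self):
        bad = dict(GP_FULL, orthopedic_disorder=True)
        assert classify_condition(None, "growing_pains", bad) is Tristate.CONTROL

    def test_iron_deficiency_requires_doctor_diagnosis(self):
        items = dict(ever_iron_deficiency=True, doctor_diagnosed=False)
        assert classify_condition(None, "iron_deficiency_history", items) is Tristate.CONTROL
        items["doctor_diagnosed"] = True
        assert classify_condition(None, "iron_deficiency_history", items) is Tristate.CASE

    def test_restless_legs_requires_all_criteria(self):
        items = dict(urge_to_move_at_rest=True, worse_at_rest=True,
                     relieved_by_movement=True, worse_evening_or_night=True)
        assert classify_condition(None, "restless_legs", items) is Tristate.CASE
        items["relieved_by_movement"] = False
        assert classify_condition(None, "restless_legs", items) is Tristate.CONTROL

    @pytest.mark.parametrize("condition,items", [
        ("migraine", {k: v for k, v in MIGRAINE_FULL.items() if k != "pulsating"}),
        ("growing_pains", {k: v for k, v in GP_FULL.items() if k != "onset_age"}),
        ("iron_deficiency_history", {"ever_iron_deficiency": True}),
        ("restless_legs", {"urge_to_move_at_rest": True}),
        ("recurrent_abdominal_pain", {}),
    ])
    def test_missing_required_items_return_missing_never_control(self, condition, items):
        assert classify_condition(None, condition, items) is Tristate.MISSING

    def test_unknown_condition_raises(self):
        with pytest.raises(Exception, match="unknown condition"):
            classify_condition(None, "tennis_elbow", {})


class TestScales:
    def test_child_anxious_depression_extremes(self):
        assert score_scale([0] * 13, "anxious_depression_child") == 0
        assert score_scale([2] * 13, "anxious_depression_child") == 26

    def test_adult_maximum_is_36(self):
        assert score_scale([2] * 18, "anxious_depression_adult") == 36

    def test_sensory_midpoint_sum(self):
        assert score_scale([3] * 7, "sensory_sensitivity") == 21

    def test_out_of_range_item_rejected(self):
        with pytest.raises(ScaleError):
            score_scale([0] * 7, "sensory_sensitivity")
        with pytest.raises(ScaleError):
            score_scale([3] * 18, "anxious_depression_adult")

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ScaleError, match="7 items"):
            score_scale([3] * 6, "sensory_sensitivity")
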