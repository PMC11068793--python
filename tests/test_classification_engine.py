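"""Case definition, staging, grading, extent, gingival and implant rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from periodx.chart_model import (
    PatientProfile,
    SiteMeasurement,
    ToothRecord,
    summarize,
)
from periodx.classification_engine import (
    ClassificationError,
    assign_extent,
    assign_grade,
    assign_stage,
    classify_gingival_status,
    classify_implants,
    diagnose,
    is_periodontitis_case,
)
from periodx.synth_cohort import chart_for_diagnosis, reachable_primary_labels

from conftest import SITE_ORDER, diseased_tooth, healthy_tooth, make_chart


def _profile(**kw):
    kw.setdefault("age_years", 50)
    return PatientProfile(**kw)


class TestCaseDefinition:
    def test_two_nonadjacent_interdental_teeth_fire_case(self):
        chart = make_chart({3: diseased_tooth(3, cal=2, pd=4),
                            19: diseased_tooth(19, cal=2, pd=4)})
        ev = is_periodontitis_case(chart)
        assert ev.rule_used == "interdental_rule"
        assert ev.qualifying_interdental_teeth == frozenset({3, 19})

    def test_two_adjacent_teeth_are_not_a_case(self):
        chart = make_chart({8: diseased_tooth(8, cal=6, pd=6),
                            9: diseased_tooth(9, cal=6, pd=6)})
        assert not is_periodontitis_case(chart).is_case

    def test_buccal_lingual_rule_without_interdental_cal(self):
        def buccal_tooth(n):
            sites = tuple(
                SiteMeasurement(site_id=s, probing_depth_mm=3,
                                recession_mm=0 if s == "B" else -3)
                for s in SITE_ORDER
            )
            return ToothRecord(tooth_number=n, sites=sites, bone_loss_percent=20.0)

        chart = make_chart({6: buccal_tooth(6), 11: buccal_tooth(11)})
        ev = is_periodontitis_case(chart)
        assert ev.rule_used == "buccal_lingual_rule"
        assert ev.qualifying_buccal_lingual_teeth == frozenset({6, 11})

    def test_single_qualifying_tooth_is_not_a_case(self):
        assert not is_periodontitis_case(
            make_chart({3: diseased_tooth(3, cal=6, pd=6)})
        ).is_case


def _case_chart(cal, pd, teeth=(3, 19), bone_loss=30.0, missing=(), **tooth_kwargs):
    return make_chart(
        {n: diseased_tooth(n, cal=cal, pd=pd, bone_loss=bone_loss, **tooth_kwargs)
         for n in teeth},
        missing=missing,
    )


class TestStage:
    @pytest.mark.parametrize(
        "cal,pd,expected",
        [(2, 4, "I"), (4, 5, "II"), (6, 7, "III")],
    )
    def test_severity_bands(self, cal, pd, expected):
        chart = _case_chart(cal, pd)
        stage, _ = assign_stage(summarize(chart), chart.profile)
        assert stage == expected

    def test_tooth_loss_forces_stage_iv(self):
        chart = make_chart(
            {n: diseased_tooth(n, cal=6, pd=6) for n in (3, 19)},
            profile=_profile(teeth_lost_to_periodontitis=5),
            missing=(1, 2, 15, 16, 17),
        )
        stage, rationale = assign_stage(summarize(chart), chart.profile)
        assert stage == "IV"
        assert "S.stage_iv_tooth_loss" in rationale

    def test_deep_pockets_shift_stage_up(self):
        # CAL severity says II but a 6 mm pocket forces at least III
        chart = _case_chart(cal=4, pd=6)
        stage, rationale = assign_stage(summarize(chart), chart.profile)
        assert stage == "III"
        assert "S.complexity_shift_up" in rationale

    def test_boundary_cal_2_to_3_flips_stage(self):
        s1, _ = assign_stage(summarize(_case_chart(2, 4)), _profile())
        s2, _ = assign_stage(summarize(_case_chart(3, 4)), _profile())
        assert (s1, s2) == ("I", "II")

    def test_boundary_cal_4_to_5_flips_stage(self):
        s1, _ = assign_stage(summarize(_case_chart(4, 5)), _profile())
        s2, _ = assign_stage(summarize(_case_chart(5, 5)), _profile())
        assert (s1, s2) == ("II", "III")

    def test_non_case_rejected(self):
        chart = make_chart()
        with pytest.raises(ClassificationError):
            assign_stage(summarize(chart), chart.profile)


class TestGrade:
    def test_ratio_one_is_grade_b_closed_interval(self):
        chart = _case_chart(6, 6, bone_loss=50.0)
        grade, _ = assign_grade(summarize(chart), _profile(age_years=50))
        assert grade == "B"

    def test_ratio_quarter_is_grade_b_closed_interval(self):
        chart = _case_chart(6, 6, bone_loss=10.0)
        grade, _ = assign_grade(summarize(chart), _profile(age_years=40))
        assert grade == "B"

    def test_high_ratio_is_grade_c(self):
        chart = _case_chart(6, 6, bone_loss=35.0)
        grade, _ = assign_grade(summarize(chart), _profile(age_years=25))
        assert grade == "C"

    def test_heavy_smoking_upgrades_to_c(self):
        chart = _case_chart(6, 6, bone_loss=10.0)  # ratio 0.2 -> A on its own
        grade, rationale = assign_grade(
            summarize(chart), _profile(smoking_cigarettes_per_day=15)
        )
        assert grade == "C"
        assert "G.smoking_heavy" in rationale

    def test_light_smoking_upgrades_only_to_b(self):
        chart = _case_chart(6, 6, bone_loss=10.0)
        grade, _ = assign_grade(summarize(chart), _profile(smoking_cigarettes_per_day=5))
        assert grade == "B"

    def test_controlled_diabetes_at_least_b_high_hba1c_c(self):
        chart = _case_chart(6, 6, bone_loss=10.0)
        g1, _ = assign_grade(summarize(chart), _profile(has_diabetes=True))
        g2, _ = assign_grade(summarize(chart),
                             _profile(has_diabetes=True, hba1c_percent=8.2))
        assert (g1, g2) == ("B", "C")

    def test_modifiers_never_downgrade(self):
        chart = _case_chart(6, 6, bone_loss=70.0)  # ratio 1.4 -> C
        grade, _ = assign_grade(summarize(chart), _profile(smoking_cigarettes_per_day=5))
        assert grade == "C"

    def test_missing_bone_loss_errors(self):
        chart = make_chart({
            3: diseased_tooth(3, cal=6, pd=6, bone_loss=None),
            19: diseased_tooth(19, cal=6, pd=6, bone_loss=None),
        })
        bare = {
            n: ToothRecord(tooth_number=n, sites=chart.teeth[n].sites)
            for n in range(1, 33)
        }
        chart = make_chart(bare)
        with pytest.raises(ClassificationError, match="grading evidence missing"):
            assign_grade(summarize(chart), chart.profile)


class TestExtent:
    def test_localized_below_30_percent(self):
        chart = _case_chart(6, 6, teeth=(3, 7, 19, 28))
        extent, _ = assign_extent(summarize(chart))
        assert extent == "localized"

    def test_generalized_at_or_above_30_percent(self):
        teeth = (2, 4, 6, 8, 10, 12, 19, 21, 23, 25, 27, 29)
        chart = _case_chart(6, 6, teeth=teeth)
        extent, _ = assign_extent(summarize(chart))
        assert extent == "generalized"

    def test_molar_incisor_pattern_takes_precedence(self):
        chart = _case_chart(6, 6, teeth=(3, 14, 19, 30, 8, 9, 25))
        extent, _ = assign_extent(summarize(chart))
        assert extent == "molar_incisor_pattern"

    def test_molars_only_is_not_the_pattern(self):
        chart = _case_chart(6, 6, teeth=(3, 14, 19, 30))
        extent, _ = assign_extent(summarize(chart))
        assert extent == "localized"


class TestGingivalStatus:
    def test_low_bop_no_cal_is_intact_health(self):
        chart = make_chart({5: healthy_tooth(5, bop=("MB",))})
        diag = classify_gingival_status(summarize(chart), chart.profile)
        assert diag.category == "clinical_gingival_health_intact"

    def test_low_bop_with_cal_is_reduced_health(self):
        chart = make_chart({5: diseased_tooth(5, cal=2, pd=4)})
        diag = classify_gingival_status(summarize(chart), chart.profile)
        assert diag.category == "clinical_gingival_health_reduced"

    def test_high_bop_is_generalized_gingivitis(self):
        overrides = {n: healthy_tooth(n, bop=SITE_ORDER[:3]) for n in range(1, 33)}
        chart = make_chart(overrides)  # 50% of sites bleed
        diag = classify_gingival_status(summarize(chart), chart.profile)
        assert diag.category == "gingivitis"
        assert "H.gingivitis_generalized" in diag.rationale


class TestImplants:
    def _implant(self, n, bop=False, sup=False, progressive=False):
        sites = tuple(
            SiteMeasurement(site_id=s, probing_depth_mm=3, bleeding_on_probing=bop,
                            suppuration=sup)
            for s in ("MB", "B", "DB", "L")
        )
        flags = frozenset({"progressive_bone_loss"}) if progressive else frozenset()
        return ToothRecord(tooth_number=n, is_implant=True, sites=sites, flags=flags)

    def test_quiet_implant_is_healthy(self):
        out = classify_implants(make_chart({19: self._implant(19)}))
        assert [d.category for d in out] == ["peri_implant_health"]

    def test_bleeding_without_bone_loss_is_mucositis(self):
        out = classify_implants(make_chart({19: self._implant(19, bop=True)}))
        assert out[0].category == "peri_implant_mucositis"

    def test_progressive_bone_loss_is_peri_implantitis(self):
        out = classify_implants(make_chart({19: self._implant(19, bop=True, progressive=True)}))
        assert out[0].category == "peri_implantitis"

    def test_no_implants_yields_empty_list(self):
        assert classify_implants(make_chart()) == []


class TestDiagnose:
    def test_healthy_chart_full_report(self):
        report = diagnose(make_chart())
        assert report.primary.category == "clinical_gingival_health_intact"
        assert report.secondary == ()
        assert report.treatment_options
        assert report.rationale

    def test_severe_chart_with_restorations(self):
        chart = make_chart(
            {n: diseased_tooth(n, cal=7, pd=7, bone_loss=70.0,
                               flags=frozenset({"defective_restoration"}))
             for n in (2, 4, 6, 8, 10, 12, 19, 21, 23, 25, 27, 29)},
            profile=_profile(age_years=48, teeth_lost_to_periodontitis=5),
            missing=(1, 15, 16, 17, 32),
        )
        report = diagnose(chart)
        assert report.primary.label == "generalized periodontitis stage IV grade C"
        assert any(s.category == "tooth_prosthesis_related_factors" for s in report.secondary)

    def test_deterministic(self):
        chart = chart_for_diagnosis("localized periodontitis stage III grade B", seed=5)
        assert diagnose(chart) == diagnose(chart)

    def test_every_tabulated_label_reachable(self):
        for label in reachable_primary_labels():
            chart = chart_for_diagnosis(label, seed=1)
            primary = diagnose(chart).primary
            assert label in (primary.label, primary.category)


@given(extra=st.integers(0, 3), seed=st.integers(0, 50))
@settings(max_examples=40, deadline=None)
def test_stage_monotone_in_recession(extra, seed):
    """Adding recession (hence CAL) at the worst site never lowers the stage."""
    from dataclasses import replace

    order = {"I": 1, "II": 2, "III": 3, "IV": 4}
    base = chart_for_diagnosis("localized periodontitis stage II grade B", seed=seed)
    s0, _ = assign_stage(summarize(base), base.profile)
    teeth = dict(base.teeth)
    worst = max(
        (r for r in base.present_natural_teeth()),
        key=lambda r: max((s.probing_depth_mm + s.recession_mm for s in r.sites)),
    )
    bumped = replace(
        worst,
        sites=tuple(replace(s, recession_mm=min(15, s.recession_mm + extra)) for s in worst.sites),
    )
    teeth[worst.tooth_number] = bumped
    chart = replace(base, teeth=teeth)
    s1, _ = assign_stage(summarize(chart), chart.profile)
    assert order[s1] >= order[s0]
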