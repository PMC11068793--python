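"""Deterministic 2017 AAP/EFP classification logic.

The engine decides, from a summarized full-mouth chart and the patient
profile:

* whether the dentition meets the periodontitis case definition
  (interproximal CAL on >= 2 non-adjacent teeth, or buccal/lingual CAL
  >= 3 mm on >= 2 teeth);
* if so, the stage (I-IV; severity from worst interdental CAL with
  complexity factors shifting the stage up), grade (A-C; radiographic bone
  loss / age ratio with smoking and diabetes as upgrade-only modifiers) and
  extent (localized / generalized at a 30% cut-off, or molar-incisor
  pattern);
* otherwise the gingival status (clinical gingival health on an intact or
  reduced periodontium, or gingivitis by bleeding fraction);
* and, independently, the peri-implant status of every implant.

Every decision appends a stable rule identifier to the diagnosis rationale,
in firing order, so a report can be audited rule by rule. All numeric
thresholds come from :mod:`periodx.config`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .chart_model import (
    BUCCAL_LINGUAL_SITES,
    ChartError,
    ChartSummary,
    FIRST_SECOND_MOLARS,
    INCISORS,
    INTERPROXIMAL_SITES,
    PatientProfile,
    PeriodontalChart,
    compute_cal,
    summarize,
    teeth_adjacent,
)
from .config import ClinicalConfig, default_config

PERIODONTITIS_CATEGORIES = ("periodontitis",)
GINGIVAL_CATEGORIES = (
    "clinical_gingival_health_intact",
    "clinical_gingival_health_reduced",
    "gingivitis",
)
IMPLANT_CATEGORIES = ("peri_implant_health", "peri_implant_mucositis", "peri_implantitis")
_IMPLANT_SEVERITY = {c: i for i, c in enumerate(IMPLANT_CATEGORIES)}

STAGES = ("I", "II", "III", "IV")
GRADES = ("A", "B", "C")
EXTENTS = ("localized", "generalized", "molar_incisor_pattern")


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class PrimaryDiagnosis:
    category: str
    extent: str = "none"
    stage: str = "none"
    grade: str = "none"
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        is_perio = self.category == "periodontitis"
        components_set = "none" not in (self.stage, self.grade, self.extent)
        if is_perio != components_set:
            raise ClassificationError(
                "stage/grade/extent must all be set for periodontitis and only for periodontitis"
            )
        if not self.rationale:
            raise ClassificationError("every diagnosis must carry at least one rationale entry")

    @property
    def label(self) -> str:
        if self.category == "periodontitis":
            extent = "molar-incisor pattern" if self.extent == "molar_incisor_pattern" else self.extent
            return f"{extent} periodontitis stage {self.stage} grade {self.grade}"
        return self.category

    def key(self) -> tuple[str, str, str, str]:
        return (self.category, self.extent, self.stage, self.grade)


@dataclass(frozen=True)
class CaseEvidence:
    qualifying_interdental_teeth: frozenset[int]
    qualifying_buccal_lingual_teeth: frozenset[int]
    rule_used: str  # interdental_rule | buccal_lingual_rule | none

    @property
    def is_case(self) -> bool:
        return self.rule_used != "none"


def _has_nonadjacent_pair(teeth: frozenset[int]) -> bool:
    return any(not teeth_adjacent(a, b) for a, b in combinations(sorted(teeth), 2))


def is_periodontitis_case(chart: PeriodontalChart, config: ClinicalConfig | None = None) -> CaseEvidence:
    """Apply the case definition; the interdental rule takes precedence."""
    config = config or default_config()
    cal_min = config.case_interdental_cal_min_mm
    bl_min = config.case_buccal_lingual_cal_min_mm

    interdental: set[int] = set()
    buccal_lingual: set[int] = set()
    for rec in chart.present_natural_teeth():
        for s in rec.sites:
            cal = compute_cal(s)
            if s.site_id in INTERPROXIMAL_SITES and cal >= cal_min:
                interdental.add(rec.tooth_number)
            elif s.site_id in BUCCAL_LINGUAL_SITES and cal >= bl_min:
                buccal_lingual.add(rec.tooth_number)

    rule = "none"
    if len(interdental) >= 2 and _has_nonadjacent_pair(frozenset(interdental)):
        rule = "interdental_rule"
    elif len(buccal_lingual) >= config.case_buccal_lingual_min_teeth:
        rule = "buccal_lingual_rule"
    return CaseEvidence(
        qualifying_interdental_teeth=frozenset(interdental),
        qualifying_buccal_lingual_teeth=frozenset(buccal_lingual),
        rule_used=rule,
    )


def _severity_cal(summary: ChartSummary) -> int:
    # worst interproximal CAL; a purely buccal/lingual case falls back to
    # the worst mid-facial CAL so severity is still defined
    return summary.max_interdental_cal_mm or summary.max_cal_mm_buccal_lingual


def assign_stage(summary: ChartSummary, profile: PatientProfile,
                 config: ClinicalConfig | None = None) -> tuple[str, list[str]]:
    """Stage I-IV: CAL severity band, complexity shift-up, then III vs IV."""
    config = config or default_config()
    if not summary.affected_teeth and not summary.buccal_lingual_case_teeth:
        raise ClassificationError("assign_stage called on a chart that is not a periodontitis case")
    rationale: list[str] = []
    cal = _severity_cal(summary)
    i_lo, i_hi = config.stage_i_cal_range
    ii_lo, ii_hi = config.stage_ii_cal_range
    if cal >= config.stage_iii_cal_min:
        severity, rid = "III", f"S.severity_CAL_ge_{config.stage_iii_cal_min}"
    elif ii_lo <= cal <= ii_hi:
        severity, rid = "II", f"S.severity_CAL_{ii_lo}_{ii_hi}"
    else:
        severity, rid = "I", f"S.severity_CAL_{i_lo}_{i_hi}"
    rationale.append(rid)

    stage = severity
    if (
        summary.max_probing_depth_mm >= config.complexity_pd_min_mm
        or summary.max_furcation_class >= config.complexity_furcation_min_class
        or summary.has_vertical_defect
    ):
        if STAGES.index(stage) < STAGES.index("III"):
            stage = "III"
        rationale.append("S.complexity_shift_up")

    if stage == "III":
        remaining = summary.scorable_teeth_count
        if profile.teeth_lost_to_periodontitis >= config.stage_iv_teeth_lost_min:
            stage = "IV"
            rationale.append("S.stage_iv_tooth_loss")
        elif remaining < config.stage_iv_remaining_teeth_below:
            stage = "IV"
            rationale.append("S.stage_iv_few_remaining_teeth")
        elif profile.masticatory_dysfunction:
            stage = "IV"
            rationale.append("S.stage_iv_masticatory_dysfunction")
    return stage, rationale


def assign_grade(summary: ChartSummary, profile: PatientProfile,
                 config: ClinicalConfig | None = None) -> tuple[str, list[str]]:
    """Grade A-C from %bone-loss/age, upgraded (never downgraded) by risk factors."""
    config = config or default_config()
    if summary.worst_bone_loss_percent is None:
        raise ClassificationError("grading evidence missing: no radiographic bone loss recorded")
    rationale: list[str] = []
    r = summary.worst_bone_loss_percent / profile.age_years
    if r < config.grade_ratio_a_below:
        grade = "A"
    elif r <= config.grade_ratio_c_above:
        grade = "B"
    else:
        grade = "C"
    rationale.append(f"G.bone_loss_age_ratio_{grade}")

    def upgrade(to: str, rid: str) -> None:
        nonlocal grade
        if GRADES.index(to) > GRADES.index(grade):
            grade = to
        rationale.append(rid)

    smoke = profile.smoking_cigarettes_per_day
    if smoke >= config.smoking_grade_c_min_per_day:
        upgrade("C", "G.smoking_heavy")
    elif smoke > 0:
        upgrade("B", "G.smoking_light")
    if profile.has_diabetes:
        if profile.hba1c_percent is not None and profile.hba1c_percent >= config.hba1c_grade_c_min_percent:
            upgrade("C", "G.diabetes_hba1c_high")
        else:
            upgrade("B", "G.diabetes")
    return grade, rationale


def assign_extent(summary: ChartSummary, config: ClinicalConfig | None = None) -> tuple[str, list[str]]:
    """Extent: molar-incisor pattern takes precedence, else 30% cut-off."""
    config = config or default_config()
    if summary.scorable_teeth_count == 0:
        raise ClassificationError("extent undefined: no scorable teeth")
    affected = summary.affected_teeth or summary.buccal_lingual_case_teeth
    allowed = FIRST_SECOND_MOLARS | INCISORS
    if (
        affected
        and affected <= allowed
        and affected & FIRST_SECOND_MOLARS
        and affected & INCISORS
    ):
        return "molar_incisor_pattern", ["E.molar_incisor_pattern"]
    f = len(affected) / summary.scorable_teeth_count
    if f >= config.generalized_min_fraction:
        return "generalized", ["E.generalized_ge_30pct"]
    return "localized", ["E.localized_lt_30pct"]


def classify_gingival_status(summary: ChartSummary, profile: PatientProfile,
                             config: ClinicalConfig | None = None) -> PrimaryDiagnosis:
    """Non-case natural dentition: gingival health vs gingivitis by BOP fraction."""
    config = config or default_config()
    bop = summary.bleeding_site_fraction
    if bop < config.gingivitis_bop_min_fraction:
        if summary.any_cal_or_bone_loss:
            return PrimaryDiagnosis(
                category="clinical_gingival_health_reduced",
                rationale=("H.bop_below_10pct", "H.reduced_periodontium"),
            )
        return PrimaryDiagnosis(
            category="clinical_gingival_health_intact",
            rationale=("H.bop_below_10pct", "H.intact_periodontium"),
        )
    annotation = (
        "H.gingivitis_generalized"
        if bop > config.generalized_gingivitis_bop_fraction
        else "H.gingivitis_localized"
    )
    return PrimaryDiagnosis(category="gingivitis", rationale=("H.bop_ge_10pct", annotation))


def classify_implants(chart: PeriodontalChart, config: ClinicalConfig | None = None) -> list[PrimaryDiagnosis]:
    """Per-implant status; empty list when the chart has no implants."""
    out: list[PrimaryDiagnosis] = []
    for imp in sorted(chart.implants(), key=lambda r: r.tooth_number):
        bop = any(s.bleeding_on_probing for s in imp.sites)
        sup = any(s.suppuration for s in imp.sites)
        progressive = "progressive_bone_loss" in imp.flags
        if progressive:
            cat, rid = "peri_implantitis", "I.progressive_bone_loss"
        elif bop or sup:
            cat, rid = "peri_implant_mucositis", "I.inflammation_no_bone_loss"
        else:
            cat, rid = "peri_implant_health", "I.no_inflammation"
        out.append(PrimaryDiagnosis(category=cat, rationale=(f"I.implant_{imp.tooth_number}", rid)))
    return out


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

TREATMENT_TEXT = {
    "clinical_gingival_health_intact": [
        "Routine prophylaxis and oral hygiene reinforcement",
        "Periodic periodontal evaluation",
    ],
    "clinical_gingival_health_reduced": [
        "Supportive periodontal therapy at individualized intervals",
        "Oral hygiene reinforcement and risk-factor control",
    ],
    "gingivitis": [
        "Professional mechanical plaque removal",
        "Oral hygiene instruction and re-evaluation in 4-6 weeks",
    ],
    "periodontitis": [
        "Step 1: oral hygiene, risk-factor control, supragingival debridement",
        "Step 2: subgingival instrumentation",
        "Step 3: reassessment; surgical therapy for residual deep pockets",
        "Step 4: supportive periodontal care",
    ],
    "peri_implant_health": ["Routine implant maintenance"],
    "peri_implant_mucositis": [
        "Submarginal biofilm removal around the implant",
        "Oral hygiene reinforcement and re-evaluation",
    ],
    "peri_implantitis": [
        "Anti-infective therapy; surgical access as indicated",
        "Consider referral to a periodontist",
    ],
}


@dataclass(frozen=True)
class DiagnosisReport:
    chart_id: str
    primary: PrimaryDiagnosis
    implants: tuple[PrimaryDiagnosis, ...] = ()
    secondary: tuple = ()
    treatment_options: tuple[str, ...] = ()
    rationale: tuple[str, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "chart_id": self.chart_id,
            "primary": {
                "category": self.primary.category,
                "extent": self.primary.extent,
                "stage": self.primary.stage,
                "grade": self.primary.grade,
                "label": self.primary.label,
            },
            "implants": [
                {"category": d.category, "rationale": list(d.rationale)} for d in self.implants
            ],
            "secondary": [
                {"category": s.category, "teeth": sorted(s.teeth), "rationale": list(s.rationale)}
                for s in self.secondary
            ],
            "treatment_options": list(self.treatment_options),
            "rationale": list(self.rationale),
        }


def diagnose(chart: PeriodontalChart, config: ClinicalConfig | None = None) -> DiagnosisReport:
    """Full diagnostic pass: primary status, implants, secondary findings.

    Deterministic: identical input yields an identical report. A dentition
    with no natural teeth takes its primary status from the worst implant.
    """
    from .secondary_findings import detect_secondary  # local import to avoid a cycle

    config = config or default_config()
    summary = summarize(
        chart,
        interdental_cal_case_mm=config.case_interdental_cal_min_mm,
        buccal_lingual_cal_case_mm=config.case_buccal_lingual_cal_min_mm,
    )
    implants = tuple(classify_implants(chart, config))
    rationale: list[str] = []

    if summary.scorable_teeth_count == 0:
        if not implants:
            raise ClassificationError(f"chart {chart.chart_id}: nothing to diagnose")
        worst = max(implants, key=lambda d: _IMPLANT_SEVERITY[d.category])
        primary = PrimaryDiagnosis(
            category=worst.category,
            rationale=("R.no_natural_teeth",) + worst.rationale,
        )
        rationale.extend(primary.rationale)
    else:
        evidence = is_periodontitis_case(chart, config)
        if evidence.is_case:
            rationale.append(f"C.{evidence.rule_used}")
            extent, ext_r = assign_extent(summary, config)
            stage, stage_r = assign_stage(summary, chart.profile, config)
            grade, grade_r = assign_grade(summary, chart.profile, config)
            rationale += ext_r + stage_r + grade_r
            primary = PrimaryDiagnosis(
                category="periodontitis", extent=extent, stage=stage, grade=grade,
                rationale=tuple(rationale),
            )
        else:
            rationale.append("C.not_a_case")
            primary = classify_gingival_status(summary, chart.profile, config)
            rationale.extend(primary.rationale)
            primary = PrimaryDiagnosis(category=primary.category, rationale=tuple(rationale))

    secondary = tuple(detect_secondary(chart, config))
    for s in secondary:
        rationale.extend(s.rationale)
    return DiagnosisReport(
        chart_id=chart.chart_id,
        primary=primary,
        implants=implants,
        secondary=secondary,
        treatment_options=tuple(TREATMENT_TEXT[primary.category]),
        rationale=tuple(rationale),
    )
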