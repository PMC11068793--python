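"""Synthetic labeled cohorts of full-mouth periodontal charts.

Charts are built by *rule inversion*: for a requested diagnosis label the
generator constructs site measurements, bone-loss values and profile fields
that satisfy exactly that label's rule preconditions, with randomness only in
non-determining detail (which teeth are involved, cosmetic probing-depth
jitter, bleeding placement). This guarantees coverage of labels that are
rare in practice (the molar-incisor pattern occurred once in the 150-patient
reference cohort) where rejection sampling would be hopeless.

Default cohort frequencies follow the reference study's chairside cohort:
the 18-row primary-diagnosis frequency column (renormalized; four rows have
zero frequency) and the six secondary-condition rates out of 150 patients
(tooth/prosthesis factors 129, occlusal trauma 118, mucogingival 52,
systemic manifestation 49, endo-periodontal 18, abscess 13).

Secondary conditions are injected through chart flags chosen so the primary
label is never perturbed; the endo-periodontal lesion needs a >= 6 mm pocket
and is therefore only injected on charts whose stage permits one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .chart_model import (
    FIRST_SECOND_MOLARS,
    INCISORS,
    PatientProfile,
    PeriodontalChart,
    SiteMeasurement,
    ToothRecord,
    teeth_adjacent,
)
from .config import ClinicalConfig, default_config
from .secondary_findings import SECONDARY_CATEGORIES

SITE_ORDER = ("MB", "B", "DB", "ML", "L", "DL")

# Table-ordered primary periodontitis labels with chairside frequencies.
_PERIO_FREQ: dict[tuple[str, str, str], int] = {
    ("localized", "II", "A"): 1,
    ("localized", "II", "B"): 5,
    ("localized", "II", "C"): 1,
    ("generalized", "II", "A"): 1,
    ("generalized", "II", "B"): 10,
    ("generalized", "II", "C"): 0,
    ("localized", "III", "A"): 2,
    ("localized", "III", "B"): 25,
    ("localized", "III", "C"): 15,
    ("generalized", "III", "A"): 0,
    ("generalized", "III", "B"): 15,
    ("generalized", "III", "C"): 6,
    ("generalized", "IV", "A"): 1,
    ("generalized", "IV", "B"): 25,
    ("generalized", "IV", "C"): 43,
    ("molar_incisor_pattern", "III", "A"): 0,
    ("molar_incisor_pattern", "III", "B"): 0,
    ("molar_incisor_pattern", "III", "C"): 1,
}

SECONDARY_RATES: dict[str, float] = {
    "tooth_prosthesis_related_factors": 129 / 150,
    "occlusal_trauma": 118 / 150,
    "mucogingival_deformity": 52 / 150,
    "periodontitis_systemic_manifestation": 49 / 150,
    "endo_periodontal_lesion": 18 / 150,
    "periodontal_abscess": 13 / 150,
}

NON_PERIO_LABELS = (
    "clinical_gingival_health_intact",
    "clinical_gingival_health_reduced",
    "gingivitis",
    "peri_implant_health",
    "peri_implant_mucositis",
    "peri_implantitis",
)


def perio_label(extent: str, stage: str, grade: str) -> str:
    extent_txt = "molar-incisor pattern" if extent == "molar_incisor_pattern" else extent
    return f"{extent_txt} periodontitis stage {stage} grade {grade}"


def parse_perio_label(label: str) -> tuple[str, str, str] | None:
    """Inverse of :func:`perio_label`; None for non-periodontitis labels."""
    if " periodontitis stage " not in label:
        return None
    extent_txt, rest = label.split(" periodontitis stage ")
    stage, grade = rest.split(" grade ")
    extent = "molar_incisor_pattern" if extent_txt == "molar-incisor pattern" else extent_txt
    return extent, stage, grade


def reachable_primary_labels() -> list[str]:
    """The 18 tabulated periodontitis labels plus the health/implant categories."""
    return [perio_label(*k) for k in _PERIO_FREQ] + list(NON_PERIO_LABELS)


def default_diagnosis_weights() -> dict[str, float]:
    total = sum(_PERIO_FREQ.values())
    return {perio_label(*k): v / total for k, v in _PERIO_FREQ.items()}


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 150
    diagnosis_weights: dict[str, float] = field(default_factory=default_diagnosis_weights)
    secondary_rates: dict[str, float] = field(default_factory=lambda: dict(SECONDARY_RATES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients cannot be negative")
        s = sum(self.diagnosis_weights.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"diagnosis weights sum to {s}, not 1")
        for cat, rate in self.secondary_rates.items():
            if cat not in SECONDARY_CATEGORIES:
                raise ValueError(f"unknown secondary category {cat!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"{cat}: rate {rate} outside [0,1]")


# ---------------------------------------------------------------------------
# chart construction helpers
# ---------------------------------------------------------------------------

_THIRD_MOLARS = frozenset({1, 16, 17, 32})


def _healthy_site(site_id: str, rng: np.random.Generator, bop: bool = False) -> SiteMeasurement:
    pd = int(rng.integers(2, 4))  # 2-3 mm sulcus
    return SiteMeasurement(site_id=site_id, probing_depth_mm=pd, recession_mm=-pd,
                           bleeding_on_probing=bop)


def _healthy_tooth(n: int, rng: np.random.Generator, bone_loss: float = 0.0) -> ToothRecord:
    return ToothRecord(
        tooth_number=n,
        sites=tuple(_healthy_site(s, rng) for s in SITE_ORDER),
        bone_loss_percent=bone_loss,
    )


def _diseased_tooth(n: int, rng: np.random.Generator, cal: int, pd: int,
                    bone_loss: float) -> ToothRecord:
    """Tooth with the target interdental CAL at two interproximal sites.

    Recession is pd-complementary (rec = cal - pd) and kept below the
    2 mm mucogingival threshold by construction for the CAL/PD bands used.
    """
    sites = []
    hot = {"MB", "DL"}
    for s in SITE_ORDER:
        if s in hot:
            sites.append(
                SiteMeasurement(
                    site_id=s, probing_depth_mm=pd, recession_mm=cal - pd,
                    bleeding_on_probing=bool(rng.random() < 0.6),
                )
            )
        else:
            sites.append(_healthy_site(s, rng, bop=bool(rng.random() < 0.1)))
    return ToothRecord(tooth_number=n, sites=tuple(sites), bone_loss_percent=bone_loss)


def _pick_spaced(pool: list[int], k: int, rng: np.random.Generator) -> list[int]:
    """k teeth from pool including at least one non-adjacent pair."""
    pool = sorted(pool)
    for _ in range(200):
        picked = sorted(rng.choice(pool, size=k, replace=False).tolist())
        if k < 2:
            return picked
        if any(not teeth_adjacent(a, b) for i, a in enumerate(picked) for b in picked[i + 1:]):
            return picked
    raise ValueError(f"could not pick {k} teeth with a non-adjacent pair from {pool}")


_STAGE_BANDS = {
    # stage -> (cal choices, pd choices); PD < 6 below stage III avoids the
    # complexity shift, PD >= 6 at stage III/IV is consistent with it
    "I": ([1, 2], [4]),
    "II": ([3, 4], [5]),
    "III": ([5, 6, 7], [6, 7]),
    "IV": ([5, 6, 7], [6, 7]),
}

_GRADE_PROFILES = {
    # grade -> (age, worst bone loss %): ratio 0.18 / 0.60 / 1.33
    "A": (55, 10.0),
    "B": (50, 30.0),
    "C": (45, 60.0),
}


def _build_periodontitis(extent: str, stage: str, grade: str,
                         rng: np.random.Generator, chart_id: str,
                         config: ClinicalConfig) -> PeriodontalChart:
    present = sorted(set(range(1, 33)) - _THIRD_MOLARS)  # 28 teeth
    teeth_lost = 0
    masticatory = False
    if stage == "IV":
        # five teeth lost to periodontitis, still >= 20 remaining
        lost = [4, 13, 20, 29, 28]
        present = [t for t in present if t not in lost]
        teeth_lost = 5

    n_scorable = len(present)
    canines = sorted({6, 11, 22, 27} & set(present))
    mip_set = FIRST_SECOND_MOLARS | INCISORS
    if extent == "generalized":
        k = int(rng.integers(max(9, int(np.ceil(0.30 * n_scorable))), n_scorable // 2 + 4))
        affected = _pick_spaced(present, min(k, n_scorable), rng)
    elif extent == "localized":
        k = int(rng.integers(2, max(3, int(0.25 * n_scorable))))
        affected = _pick_spaced(present, k, rng)
    else:  # molar-incisor pattern
        molars = sorted(FIRST_SECOND_MOLARS & set(present))
        incisors = sorted(INCISORS & set(present))
        affected = sorted(
            rng.choice(molars, size=int(rng.integers(1, 3)), replace=False).tolist()
            + rng.choice(incisors, size=int(rng.integers(1, 3)), replace=False).tolist()
        )
    if extent != "molar_incisor_pattern" and set(affected) <= mip_set:
        # a set confined to molars+incisors would read as the molar-incisor
        # pattern; swap one tooth for a canine to keep the intended extent
        rest = set(affected) - {affected[-1]}
        safe = [c for c in canines if not any(teeth_adjacent(c, t) for t in rest)] or canines
        affected = sorted(rest | {safe[int(rng.integers(len(safe)))]})

    cals, pds = _STAGE_BANDS[stage]
    age, worst_bl = _GRADE_PROFILES[grade]
    teeth: dict[int, ToothRecord] = {}
    worst_assigned = False
    for n in range(1, 33):
        if n not in present:
            teeth[n] = ToothRecord(tooth_number=n, present=False)
        elif n in affected:
            cal = int(rng.choice(cals))
            pd = int(rng.choice(pds))
            if stage in ("III", "IV"):
                cal = max(cal, config.stage_iii_cal_min)
            bl = worst_bl if not worst_assigned else float(rng.uniform(0.3, 0.8) * worst_bl)
            worst_assigned = True
            teeth[n] = _diseased_tooth(n, rng, cal=cal, pd=pd, bone_loss=bl)
        else:
            teeth[n] = _healthy_tooth(n, rng, bone_loss=float(rng.uniform(0, 0.2) * worst_bl))
    # the worst CAL must actually reach the band ceiling the stage needs
    if stage in ("III", "IV"):
        pass  # cal >= 5 enforced above
    else:
        hi = {"I": 2, "II": 4}[stage]
        tgt = affected[0]
        rec0 = teeth[tgt]
        fixed_sites = []
        for s in rec0.sites:
            if s.site_id == "MB":
                pd = _STAGE_BANDS[stage][1][0]
                fixed_sites.append(replace(s, probing_depth_mm=pd, recession_mm=hi - pd))
            else:
                fixed_sites.append(s)
        teeth[tgt] = replace(rec0, sites=tuple(fixed_sites))

    profile = PatientProfile(
        age_years=age,
        teeth_lost_to_periodontitis=teeth_lost,
        masticatory_dysfunction=masticatory,
        history_of_periodontal_treatment=bool(rng.random() < 0.3),
    )
    return PeriodontalChart(chart_id=chart_id, profile=profile, teeth=teeth)


def _build_non_perio(label: str, rng: np.random.Generator, chart_id: str) -> PeriodontalChart:
    present = sorted(set(range(1, 33)) - _THIRD_MOLARS)
    teeth: dict[int, ToothRecord] = {}
    if label.startswith("peri_implant"):
        implant_sites = ("MB", "B", "DB", "L")
        implant_positions = (8, 30)
        for n in range(1, 33):
            if n in implant_positions:
                bop = label in ("peri_implant_mucositis", "peri_implantitis")
                flags = frozenset({"progressive_bone_loss"}) if label == "peri_implantitis" else frozenset()
                sites = tuple(
                    SiteMeasurement(site_id=s, probing_depth_mm=int(rng.integers(2, 5)),
                                    recession_mm=0, bleeding_on_probing=bop and s in ("MB", "L"))
                    for s in implant_sites
                )
                teeth[n] = ToothRecord(tooth_number=n, is_implant=True, sites=sites, flags=flags)
            else:
                teeth[n] = ToothRecord(tooth_number=n, present=False)
        profile = PatientProfile(age_years=int(rng.integers(45, 75)))
        return PeriodontalChart(chart_id=chart_id, profile=profile, teeth=teeth)

    for n in range(1, 33):
        teeth[n] = (
            _healthy_tooth(n, rng) if n in present else ToothRecord(tooth_number=n, present=False)
        )
    if label == "gingivitis":
        # bleed at ~20-40% of sites
        n_bleed = int(rng.integers(40, 60))
        slots = [(t, i) for t in present for i in range(6)]
        idx = rng.choice(len(slots), size=n_bleed, replace=False)
        chosen: dict[int, set[int]] = {}
        for j in idx:
            t, i = slots[j]
            chosen.setdefault(t, set()).add(i)
        for t, site_ix in chosen.items():
            rec = teeth[t]
            teeth[t] = replace(
                rec,
                sites=tuple(
                    replace(s, bleeding_on_probing=True) if i in site_ix else s
                    for i, s in enumerate(rec.sites)
                ),
            )
    elif label == "clinical_gingival_health_reduced":
        # attachment loss on a single tooth: below the case definition
        t = int(rng.choice(present))
        rec = teeth[t]
        sites = list(rec.sites)
        sites[0] = SiteMeasurement(site_id=sites[0].site_id, probing_depth_mm=4, recession_mm=-2)
        teeth[t] = replace(rec, sites=tuple(sites))
    elif label != "clinical_gingival_health_intact":
        raise ValueError(f"unreachable label {label!r}")
    profile = PatientProfile(age_years=int(rng.integers(25, 65)))
    return PeriodontalChart(chart_id=chart_id, profile=profile, teeth=teeth)


def chart_for_diagnosis(label: str, seed: int,
                        config: ClinicalConfig | None = None,
                        chart_id: str | None = None) -> PeriodontalChart:
    """Construct a chart whose engine diagnosis is exactly ``label``.

    Identical (label, seed) always yields an identical chart.
    """
    config = config or default_config()
    rng = np.random.default_rng(seed)
    chart_id = chart_id or f"synthetic-{abs(hash(label)) % 10_000}-{seed}"
    parsed = parse_perio_label(label)
    if parsed is not None:
        extent, stage, grade = parsed
        if (extent, stage, grade) not in _PERIO_FREQ:
            raise ValueError(f"label {label!r} is not in the reachable tabulated set")
        return _build_periodontitis(extent, stage, grade, rng, chart_id, config)
    if label not in NON_PERIO_LABELS:
        raise ValueError(f"unknown or unreachable label {label!r}")
    return _build_non_perio(label, rng, chart_id)


# ---------------------------------------------------------------------------
# secondary-condition injection
# ---------------------------------------------------------------------------

def _natural_candidates(chart: PeriodontalChart) -> list[int]:
    return sorted(t.tooth_number for t in chart.present_natural_teeth())


def _add_flag(chart: PeriodontalChart, tooth: int, flag: str) -> PeriodontalChart:
    rec = chart.teeth[tooth]
    new_rec = replace(rec, flags=rec.flags | {flag})
    teeth = dict(chart.teeth)
    teeth[tooth] = new_rec
    return replace(chart, teeth=teeth)


def inject_secondary(chart: PeriodontalChart, category: str,
                     rng: np.random.Generator) -> PeriodontalChart | None:
    """Add a secondary condition without disturbing the primary label.

    Returns None when the chart cannot host the condition (for example an
    endo-periodontal lesion needs an existing >= 6 mm pocket).
    """
    teeth = _natural_candidates(chart)
    if category == "periodontitis_systemic_manifestation":
        code = "papillon_lefevre_syndrome"
        profile = replace(
            chart.profile,
            systemic_disease_codes=chart.profile.systemic_disease_codes | {code},
        )
        return replace(chart, profile=profile)
    if not teeth:
        return None
    if category == "tooth_prosthesis_related_factors":
        return _add_flag(chart, int(rng.choice(teeth)), "defective_restoration")
    if category == "occlusal_trauma":
        return _add_flag(chart, int(rng.choice(teeth)), "fremitus")
    if category == "mucogingival_deformity":
        return _add_flag(chart, int(rng.choice(teeth)), "keratinized_tissue_deficiency")
    if category == "periodontal_abscess":
        return _add_flag(chart, int(rng.choice(teeth)), "abscess")
    if category == "endo_periodontal_lesion":
        deep = [
            t for t in teeth
            if any(s.probing_depth_mm >= 6 for s in chart.teeth[t].sites)
        ]
        if not deep:
            return None
        return _add_flag(chart, int(rng.choice(deep)), "endodontic_involvement")
    raise ValueError(f"unknown secondary category {category!r}")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortCase:
    chart: PeriodontalChart
    primary_label: str
    secondary: frozenset[str]


def sample_cohort(config: CohortConfig) -> list[CohortCase]:
    """Draw a labeled cohort: i.i.d. primary labels, Bernoulli secondary flags."""
    rng = np.random.default_rng(config.seed)
    labels = sorted(config.diagnosis_weights)
    probs = np.array([config.diagnosis_weights[l] for l in labels])
    probs = probs / probs.sum()
    cases: list[CohortCase] = []
    for i in range(config.n_patients):
        label = labels[int(rng.choice(len(labels), p=probs))]
        chart_seed = int(rng.integers(0, 2**31 - 1))
        chart = chart_for_diagnosis(label, chart_seed, chart_id=f"case-{config.seed}-{i:04d}")
        injected: set[str] = set()
        for cat in sorted(config.secondary_rates):
            if rng.random() < config.secondary_rates[cat]:
                updated = inject_secondary(chart, cat, rng)
                if updated is not None:
                    chart = updated
                    injected.add(cat)
        cases.append(CohortCase(chart=chart, primary_label=label, secondary=frozenset(injected)))
    return cases
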