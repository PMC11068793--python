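"""Rules for the six secondary periodontal condition categories.

Secondary conditions are flagged alongside the primary diagnosis and are
not mutually exclusive: a patient can carry any subset of tooth- and
prosthesis-related factors, occlusal trauma, mucogingival deformity,
periodontitis as a manifestation of systemic disease, endodontic-periodontal
lesion and periodontal abscess. Detection is a pure function of explicit
chart flags, site measurements and the patient profile, with thresholds in
the shared clinical config, so the rule set is auditable and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chart_model import PeriodontalChart, compute_cal
from .config import ClinicalConfig, default_config

SECONDARY_CATEGORIES = (
    "endo_periodontal_lesion",
    "mucogingival_deformity",
    "occlusal_trauma",
    "periodontal_abscess",
    "periodontitis_systemic_manifestation",
    "tooth_prosthesis_related_factors",
)


@dataclass(frozen=True)
class SecondaryDiagnosis:
    category: str
    teeth: frozenset[int]
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.category not in SECONDARY_CATEGORIES:
            raise ValueError(f"unknown secondary category {self.category!r}")
        if not self.teeth and self.category != "periodontitis_systemic_manifestation":
            raise ValueError(f"{self.category}: tooth-level finding needs at least one tooth")


def detect_secondary(chart: PeriodontalChart, config: ClinicalConfig | None = None) -> list[SecondaryDiagnosis]:
    """Detect every secondary category present on the chart, sorted by category."""
    config = config or default_config()
    sc = config.secondary
    tp_flags = set(sc["tooth_prosthesis_flags"])
    ot_flags = set(sc["occlusal_trauma_flags"])

    tooth_prosthesis: dict[int, list[str]] = {}
    occlusal: dict[int, list[str]] = {}
    mucogingival: dict[int, list[str]] = {}
    endo: dict[int, list[str]] = {}
    abscess: dict[int, list[str]] = {}

    for rec in chart.teeth.values():
        if not rec.present:
            continue
        n = rec.tooth_number
        hit = sorted(rec.flags & tp_flags)
        if hit:
            tooth_prosthesis[n] = [f"X.tooth_prosthesis.{f}" for f in hit]
        hit = sorted(rec.flags & ot_flags)
        if hit:
            occlusal[n] = [f"X.occlusal.{f}" for f in hit]
        if rec.mobility_class >= sc["occlusal_trauma_mobility_min_class"]:
            occlusal.setdefault(n, []).append("X.occlusal.mobility")
        if "keratinized_tissue_deficiency" in rec.flags:
            mucogingival[n] = ["X.mucogingival.keratinized_tissue_deficiency"]
        if any(s.recession_mm >= sc["mucogingival_recession_min_mm"] for s in rec.sites):
            mucogingival.setdefault(n, []).append("X.mucogingival.recession")
        if "endodontic_involvement" in rec.flags and any(
            s.probing_depth_mm >= sc["endo_perio_pd_min_mm"] for s in rec.sites
        ):
            endo[n] = ["X.endo_perio.deep_pocket_with_endo"]
        if "abscess" in rec.flags:
            abscess[n] = ["X.abscess.flag"]
        elif any(
            s.suppuration and s.probing_depth_mm >= sc["abscess_suppuration_pd_min_mm"]
            for s in rec.sites
        ):
            abscess[n] = ["X.abscess.suppuration_deep_pocket"]

    out: list[SecondaryDiagnosis] = []

    def emit(category: str, per_tooth: dict[int, list[str]]) -> None:
        if per_tooth:
            rationale = tuple(r for n in sorted(per_tooth) for r in per_tooth[n])
            out.append(SecondaryDiagnosis(category, frozenset(per_tooth), rationale))

    emit("endo_periodontal_lesion", endo)
    emit("mucogingival_deformity", mucogingival)
    emit("occlusal_trauma", occlusal)
    emit("periodontal_abscess", abscess)

    manifest = set(sc["systemic_manifestation_codes"])
    codes = sorted(chart.profile.systemic_disease_codes & manifest)
    if codes:
        out.append(
            SecondaryDiagnosis(
                "periodontitis_systemic_manifestation",
                frozenset(),
                tuple(f"X.systemic.{c}" for c in codes),
            )
        )
    emit("tooth_prosthesis_related_factors", tooth_prosthesis)
    out.sort(key=lambda d: d.category)
    return out
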