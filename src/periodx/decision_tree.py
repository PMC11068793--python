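"""Serializable diagnostic question tree with validation and traversal.

The tree mirrors the guided questionnaire style of chairside decision-support
apps: each question node carries wording, an optional expandable info text
(the "information icon"), and at least two answers; each leaf carries a
diagnosis payload plus non-empty suggested treatment options. Questions also
carry a machine-readable ``predicate`` identifier so the tree can be answered
automatically from a charted case; the predicates read the same clinical
constants as the classification engine, which is what keeps tree and engine
from drifting apart.

The node graph is a rooted DAG: several answer paths may converge on a shared
downstream question (for example the grade question for a given extent and
stage), but no cycles are permitted and every node must be reachable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

from .chart_model import ChartSummary, PatientProfile, PeriodontalChart, summarize
from .classification_engine import (
    TREATMENT_TEXT,
    CaseEvidence,
    _IMPLANT_SEVERITY,
    _severity_cal,
    classify_implants,
    is_periodontitis_case,
)
from .config import ClinicalConfig, default_config

TREE_VERSION = "default-1.0"


class TreeError(ValueError):
    pass


@dataclass(frozen=True)
class TreeNode:
    node_id: str
    kind: str  # "question" | "leaf"
    question_text: str = ""
    info_text: str = ""
    predicate: str = ""
    answers: tuple[tuple[str, str], ...] = ()  # (label, next_node_id)
    diagnosis: Mapping[str, str] | None = None
    treatment_options: tuple[str, ...] = ()
    refs: tuple[str, ...] = ()

    def answer_labels(self) -> list[str]:
        return [label for label, _ in self.answers]

    def next_for(self, label: str) -> str:
        for lab, nxt in self.answers:
            if lab == label:
                return nxt
        raise TreeError(
            f"node {self.node_id!r}: answer {label!r} not offered "
            f"(choices: {self.answer_labels()})"
        )


@dataclass(frozen=True)
class DecisionTree:
    root_id: str
    nodes: Mapping[str, TreeNode]
    version: str = TREE_VERSION
    resources: tuple[str, ...] = ()

    @property
    def root(self) -> TreeNode:
        return self.nodes[self.root_id]

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.nodes.values() if n.kind == "leaf"]


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def tree_to_dict(tree: DecisionTree) -> dict:
    nodes = {}
    for nid in sorted(tree.nodes):
        n = tree.nodes[nid]
        d: dict = {"kind": n.kind}
        if n.kind == "question":
            d.update(
                question_text=n.question_text,
                info_text=n.info_text,
                predicate=n.predicate,
                answers=[{"label": lab, "next_node_id": nxt} for lab, nxt in n.answers],
            )
        else:
            d.update(diagnosis=dict(n.diagnosis or {}), treatment_options=list(n.treatment_options))
        if n.refs:
            d["refs"] = list(n.refs)
        nodes[nid] = d
    return {
        "version": tree.version,
        "root_id": tree.root_id,
        "resources": list(tree.resources),
        "nodes": nodes,
    }


def tree_from_dict(doc: Mapping) -> DecisionTree:
    nodes: dict[str, TreeNode] = {}
    for nid, nd in doc["nodes"].items():
        nodes[nid] = TreeNode(
            node_id=nid,
            kind=nd["kind"],
            question_text=nd.get("question_text", ""),
            info_text=nd.get("info_text", ""),
            predicate=nd.get("predicate", ""),
            answers=tuple((a["label"], a["next_node_id"]) for a in nd.get("answers", ())),
            diagnosis=nd.get("diagnosis"),
            treatment_options=tuple(nd.get("treatment_options", ())),
            refs=tuple(nd.get("refs", ())),
        )
    return DecisionTree(
        root_id=doc["root_id"],
        nodes=nodes,
        version=doc.get("version", "unversioned"),
        resources=tuple(doc.get("resources", ())),
    )


def load_tree(path: str | Path) -> DecisionTree:
    with open(path, encoding="utf-8") as fh:
        return tree_from_dict(json.load(fh))


def save_tree(tree: DecisionTree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree_to_dict(tree), fh, indent=1, sort_keys=True)
        fh.write("\n")


def default_tree() -> DecisionTree:
    """The shipped question tree, loaded from packaged data."""
    text = resources.files("periodx.data").joinpath("default_tree.json").read_text()
    return tree_from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_tree(tree: DecisionTree) -> list[str]:
    """Structural audit; an empty issue list means the tree is usable."""
    issues: list[str] = []
    if tree.root_id not in tree.nodes:
        issues.append(f"root node {tree.root_id!r} does not exist")
        return issues
    for nid, n in tree.nodes.items():
        if n.kind == "question":
            if len(n.answers) < 2:
                issues.append(f"question {nid!r} offers fewer than 2 answers")
            for label, nxt in n.answers:
                if nxt not in tree.nodes:
                    issues.append(f"question {nid!r} answer {label!r} points to missing node {nxt!r}")
        elif n.kind == "leaf":
            if not n.treatment_options:
                issues.append(f"leaf {nid!r} has no treatment options (every leaf must suggest treatment)")
            if not n.diagnosis:
                issues.append(f"leaf {nid!r} carries no diagnosis payload")
        else:
            issues.append(f"node {nid!r} has unknown kind {n.kind!r}")

    # reachability + cycle detection (DFS with colors)
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {nid: WHITE for nid in tree.nodes}

    def dfs(nid: str) -> None:
        color[nid] = GRAY
        node = tree.nodes[nid]
        for _, nxt in node.answers:
            if nxt not in tree.nodes:
                continue
            if color[nxt] == GRAY:
                issues.append(f"cycle detected through node {nxt!r}")
            elif color[nxt] == WHITE:
                dfs(nxt)
        color[nid] = BLACK

    dfs(tree.root_id)
    for nid, c in color.items():
        if c == WHITE:
            issues.append(f"node {nid!r} unreachable from root")
    return issues


# ---------------------------------------------------------------------------
# Traversal
# ---------------------------------------------------------------------------

def traverse(tree: DecisionTree, answers: list[str] | tuple[str, ...]) -> TreeNode:
    """Consume answer labels from the root; pure function.

    Returns the reached leaf, or the pending question when answers run out.
    Raises TreeError on a label the current question does not offer, or on
    answers left over after a leaf.
    """
    node = tree.root
    for label in answers:
        if node.kind == "leaf":
            raise TreeError(f"leaf {node.node_id!r} reached with answers remaining")
        node = tree.nodes[node.next_for(label)]
    return node


def enumerate_paths(tree: DecisionTree) -> list[tuple[tuple[str, ...], str]]:
    """All root-to-leaf answer paths as (labels, leaf_id). Finite for valid trees."""
    out: list[tuple[tuple[str, ...], str]] = []

    def walk(nid: str, prefix: tuple[str, ...]) -> None:
        node = tree.nodes[nid]
        if node.kind == "leaf":
            out.append((prefix, nid))
            return
        for label, nxt in node.answers:
            walk(nxt, prefix + (label,))

    walk(tree.root_id, ())
    return out


# ---------------------------------------------------------------------------
# Auto-answer: resolve question predicates against a charted case
# ---------------------------------------------------------------------------

class PredicateError(ValueError):
    pass


@dataclass(frozen=True)
class _CaseFacts:
    chart: PeriodontalChart
    summary: ChartSummary
    profile: PatientProfile
    evidence: CaseEvidence
    config: ClinicalConfig


def _p_natural_teeth(f: _CaseFacts) -> str:
    return "yes" if f.summary.scorable_teeth_count > 0 else "no"


def _p_implant_worst(f: _CaseFacts) -> str:
    implants = classify_implants(f.chart, f.config)
    if not implants:
        raise PredicateError("predicate 'implant_worst_status': chart has no implants")
    worst = max(implants, key=lambda d: _IMPLANT_SEVERITY[d.category])
    return {
        "peri_implant_health": "no inflammation",
        "peri_implant_mucositis": "bleeding/suppuration without progressive bone loss",
        "peri_implantitis": "progressive bone loss",
    }[worst.category]


def _p_perio_case(f: _CaseFacts) -> str:
    return "yes" if f.evidence.is_case else "no"


def _p_bop_band(f: _CaseFacts) -> str:
    bop = f.summary.bleeding_site_fraction
    if bop < f.config.gingivitis_bop_min_fraction:
        return "<10% of sites"
    if bop > f.config.generalized_gingivitis_bop_fraction:
        return ">30% of sites"
    return "10-30% of sites"


def _p_attachment_history(f: _CaseFacts) -> str:
    return "yes" if f.summary.any_cal_or_bone_loss else "no"


def _p_extent_band(f: _CaseFacts) -> str:
    from .classification_engine import assign_extent

    extent, _ = assign_extent(f.summary, f.config)
    return {
        "localized": "localized (<30% of teeth)",
        "generalized": "generalized (>=30% of teeth)",
        "molar_incisor_pattern": "molar-incisor pattern",
    }[extent]


def _p_severity_band(f: _CaseFacts) -> str:
    cal = _severity_cal(f.summary)
    if cal >= f.config.stage_iii_cal_min:
        return ">= 5 mm"
    lo, hi = f.config.stage_ii_cal_range
    if lo <= cal <= hi:
        return "3-4 mm"
    return "1-2 mm"


def _p_complexity(f: _CaseFacts) -> str:
    s = f.summary
    hit = (
        s.max_probing_depth_mm >= f.config.complexity_pd_min_mm
        or s.max_furcation_class >= f.config.complexity_furcation_min_class
        or s.has_vertical_defect
    )
    return "yes" if hit else "no"


def _p_stage_iv(f: _CaseFacts) -> str:
    hit = (
        f.profile.teeth_lost_to_periodontitis >= f.config.stage_iv_teeth_lost_min
        or f.summary.scorable_teeth_count < f.config.stage_iv_remaining_teeth_below
        or f.profile.masticatory_dysfunction
    )
    return "yes" if hit else "no"


def _p_grade_band(f: _CaseFacts) -> str:
    if f.summary.worst_bone_loss_percent is None:
        raise PredicateError(
            "predicate 'grade_band': radiographic bone loss missing, grading evidence unavailable"
        )
    c = f.config
    r = f.summary.worst_bone_loss_percent / f.profile.age_years
    band = "A" if r < c.grade_ratio_a_below else ("B" if r <= c.grade_ratio_c_above else "C")
    order = {"A": 0, "B": 1, "C": 2}
    smoke = f.profile.smoking_cigarettes_per_day
    if smoke >= c.smoking_grade_c_min_per_day:
        band = "C"
    elif smoke > 0 and order[band] < 1:
        band = "B"
    if f.profile.has_diabetes:
        if f.profile.hba1c_percent is not None and f.profile.hba1c_percent >= c.hba1c_grade_c_min_percent:
            band = "C"
        elif order[band] < 1:
            band = "B"
    return f"grade {band}"


PREDICATES: dict[str, Callable[[_CaseFacts], str]] = {
    "natural_teeth_present": _p_natural_teeth,
    "implant_worst_status": _p_implant_worst,
    "perio_case": _p_perio_case,
    "bop_band": _p_bop_band,
    "attachment_loss_history": _p_attachment_history,
    "extent_band": _p_extent_band,
    "severity_band": _p_severity_band,
    "complexity_factors": _p_complexity,
    "stage_iv_discriminators": _p_stage_iv,
    "grade_band": _p_grade_band,
}


def auto_answer(
    tree: DecisionTree,
    chart: PeriodontalChart,
    config: ClinicalConfig | None = None,
) -> tuple[tuple[str, ...], TreeNode]:
    """Answer every question from the chart; returns (answer path, leaf).

    Deterministic. Raises PredicateError for a question whose predicate is
    unknown or cannot be resolved from the chart (for example grading with
    no recorded bone loss).
    """
    config = config or default_config()
    facts = _CaseFacts(
        chart=chart,
        summary=summarize(
            chart,
            interdental_cal_case_mm=config.case_interdental_cal_min_mm,
            buccal_lingual_cal_case_mm=config.case_buccal_lingual_cal_min_mm,
        ),
        profile=chart.profile,
        evidence=is_periodontitis_case(chart, config),
        config=config,
    )
    node = tree.root
    path: list[str] = []
    seen = 0
    while node.kind == "question":
        fn = PREDICATES.get(node.predicate)
        if fn is None:
            raise PredicateError(f"question {node.node_id!r}: unresolvable predicate {node.predicate!r}")
        label = fn(facts)
        path.append(label)
        node = tree.nodes[node.next_for(label)]
        seen += 1
        if seen > len(tree.nodes):
            raise TreeError("traversal exceeded node count; tree is cyclic")
    return tuple(path), node


# ---------------------------------------------------------------------------
# Default tree construction
# ---------------------------------------------------------------------------

_WORKSHOP_REFS = (
    "2017 World Workshop on the Classification of Periodontal and Peri-implant Diseases and Conditions",
    "Consensus reports of workgroups 1-4",
)


def build_default_tree(config: ClinicalConfig | None = None) -> DecisionTree:
    """Programmatic encoding of the classification as a question tree.

    Thresholds quoted in question/info texts are read from ``config`` so the
    wording can never disagree with the rules the engine applies.
    """
    config = config or default_config()
    nodes: dict[str, TreeNode] = {}

    def question(nid: str, text: str, predicate: str, answers: list[tuple[str, str]],
                 info: str = "") -> None:
        nodes[nid] = TreeNode(
            node_id=nid, kind="question", question_text=text, info_text=info,
            predicate=predicate, answers=tuple(answers), refs=_WORKSHOP_REFS[:1],
        )

    def leaf(nid: str, category: str, extent: str = "none", stage: str = "none",
             grade: str = "none") -> str:
        nodes[nid] = TreeNode(
            node_id=nid, kind="leaf",
            diagnosis={"category": category, "extent": extent, "stage": stage, "grade": grade},
            treatment_options=tuple(TREATMENT_TEXT[category]),
            refs=_WORKSHOP_REFS[:1],
        )
        return nid

    i_lo, i_hi = config.stage_i_cal_range
    ii_lo, ii_hi = config.stage_ii_cal_range

    # implant-only route
    question(
        "Q.implant_status",
        "What is the worst finding around the implant(s)?",
        "implant_worst_status",
        [
            ("no inflammation", leaf("L.implant.health", "peri_implant_health")),
            ("bleeding/suppuration without progressive bone loss",
             leaf("L.implant.mucositis", "peri_implant_mucositis")),
            ("progressive bone loss", leaf("L.implant.peri_implantitis", "peri_implantitis")),
        ],
        info="Peri-implant mucositis shows bleeding on probing without progressive "
             "radiographic bone loss; peri-implantitis shows progressive bone loss.",
    )

    # gingival route
    question(
        "Q.attachment_history",
        "Is there any attachment loss or radiographic bone loss (current or historical)?",
        "attachment_loss_history",
        [
            ("no", leaf("L.health.intact", "clinical_gingival_health_intact")),
            ("yes", leaf("L.health.reduced", "clinical_gingival_health_reduced")),
        ],
        info="Attachment loss without meeting the periodontitis case definition "
             "indicates a reduced periodontium.",
    )
    leaf("L.gingivitis.localized", "gingivitis")
    leaf("L.gingivitis.generalized", "gingivitis")
    question(
        "Q.bop",
        "What fraction of probed sites bleed on probing?",
        "bop_band",
        [
            ("<10% of sites", "Q.attachment_history"),
            ("10-30% of sites", "L.gingivitis.localized"),
            (">30% of sites", "L.gingivitis.generalized"),
        ],
        info=f"Bleeding on probing at >= {config.gingivitis_bop_min_fraction:.0%} of sites "
             "defines gingivitis; above "
             f"{config.generalized_gingivitis_bop_fraction:.0%} it is generalized.",
    )

    # periodontitis route, per extent
    for extent in ("localized", "generalized", "molar_incisor_pattern"):
        e = extent
        for stage in ("I", "II", "III", "IV"):
            question(
                f"Q.grade.{e}.{stage}",
                "What does the progression-rate evidence show "
                "(% bone loss / age, smoking, diabetes)?",
                "grade_band",
                [
                    (f"grade {g}", leaf(f"L.{e}.{stage}.{g}", "periodontitis", e, stage, g))
                    for g in ("A", "B", "C")
                ],
                info=f"Indirect evidence: %bone-loss/age < {config.grade_ratio_a_below} -> A, "
                     f"up to {config.grade_ratio_c_above} -> B, above -> C; "
                     f">= {config.smoking_grade_c_min_per_day} cigarettes/day or "
                     f"HbA1c >= {config.hba1c_grade_c_min_percent}% upgrades to C.",
            )
        question(
            f"Q.iv.{e}",
            "Are stage IV discriminators present (>= "
            f"{config.stage_iv_teeth_lost_min} teeth lost to periodontitis, "
            f"< {config.stage_iv_remaining_teeth_below} remaining teeth, or "
            "masticatory dysfunction)?",
            "stage_iv_discriminators",
            [("no", f"Q.grade.{e}.III"), ("yes", f"Q.grade.{e}.IV")],
        )
        for stage, band in (("I", f"{i_lo}-{i_hi} mm"), ("II", f"{ii_lo}-{ii_hi} mm")):
            question(
                f"Q.comp.{e}.{stage}",
                "Are complexity factors present (probing depth >= "
                f"{config.complexity_pd_min_mm} mm, furcation class >= "
                f"{config.complexity_furcation_min_class}, or vertical defects)?",
                "complexity_factors",
                [("no", f"Q.grade.{e}.{stage}"), ("yes", f"Q.iv.{e}")],
                info="Complexity factors raise the stage to at least III regardless "
                     "of the CAL severity band.",
            )
        question(
            f"Q.sev.{e}",
            "What is the worst interdental clinical attachment loss?",
            "severity_band",
            [
                (f"{i_lo}-{i_hi} mm", f"Q.comp.{e}.I"),
                (f"{ii_lo}-{ii_hi} mm", f"Q.comp.{e}.II"),
                (">= 5 mm", f"Q.iv.{e}"),
            ],
            info="CAL = probing depth + recession at the worst interproximal site.",
        )

    question(
        "Q.extent",
        "How is the disease distributed across the dentition?",
        "extent_band",
        [
            ("localized (<30% of teeth)", "Q.sev.localized"),
            ("generalized (>=30% of teeth)", "Q.sev.generalized"),
            ("molar-incisor pattern", "Q.sev.molar_incisor_pattern"),
        ],
        info=f"Generalized means >= {config.generalized_min_fraction:.0%} of teeth show "
             "the case-defining attachment loss; a pattern confined to first/second "
             "molars and incisors (with both involved) is the molar-incisor pattern.",
    )
    question(
        "Q.case",
        "Does the dentition meet the periodontitis case definition?",
        "perio_case",
        [("no", "Q.bop"), ("yes", "Q.extent")],
        info=f"Interproximal CAL >= {config.case_interdental_cal_min_mm} mm on >= 2 "
             "non-adjacent teeth, or buccal/lingual CAL >= "
             f"{config.case_buccal_lingual_cal_min_mm} mm on >= 2 teeth.",
    )
    question(
        "Q.root",
        "Are any natural teeth present?",
        "natural_teeth_present",
        [("yes", "Q.case"), ("no", "Q.implant_status")],
    )

    return DecisionTree(
        root_id="Q.root",
        nodes=nodes,
        version=TREE_VERSION,
        resources=_WORKSHOP_REFS,
    )
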