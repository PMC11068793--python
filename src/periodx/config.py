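"""Clinical rule constants, loaded from a single versioned JSON file.

Every threshold used by the classification engine, the secondary-findings
rules and the shipped decision tree lives in one document so the engine and
tree cannot drift apart, and so future revisions of the classification are
data edits rather than code edits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any


@dataclass(frozen=True)
class ClinicalConfig:
    """Parsed clinical-constant document.

    The raw nested mapping is kept (``raw``) for hashing/serialisation;
    frequently used thresholds are exposed as attributes.
    """

    raw: dict[str, Any] = field(repr=False)
    version: str = "unversioned"

    # -- case definition -------------------------------------------------
    @property
    def case_interdental_cal_min_mm(self) -> int:
        return self.raw["case_definition"]["interdental_cal_min_mm"]

    @property
    def case_buccal_lingual_cal_min_mm(self) -> int:
        return self.raw["case_definition"]["buccal_lingual_cal_min_mm"]

    @property
    def case_buccal_lingual_min_teeth(self) -> int:
        return self.raw["case_definition"]["buccal_lingual_min_teeth"]

    # -- staging ---------------------------------------------------------
    @property
    def stage_i_cal_range(self) -> tuple[int, int]:
        lo, hi = self.raw["staging"]["severity_cal_stage_i_mm"]
        return lo, hi

    @property
    def stage_ii_cal_range(self) -> tuple[int, int]:
        lo, hi = self.raw["staging"]["severity_cal_stage_ii_mm"]
        return lo, hi

    @property
    def stage_iii_cal_min(self) -> int:
        return self.raw["staging"]["severity_cal_stage_iii_min_mm"]

    @property
    def complexity_pd_min_mm(self) -> int:
        return self.raw["staging"]["complexity_pd_min_mm"]

    @property
    def complexity_furcation_min_class(self) -> int:
        return self.raw["staging"]["complexity_furcation_min_class"]

    @property
    def stage_iv_teeth_lost_min(self) -> int:
        return self.raw["staging"]["stage_iv_teeth_lost_min"]

    @property
    def stage_iv_remaining_teeth_below(self) -> int:
        return self.raw["staging"]["stage_iv_remaining_teeth_below"]

    # -- grading ---------------------------------------------------------
    @property
    def grade_ratio_a_below(self) -> float:
        return self.raw["grading"]["ratio_a_below"]

    @property
    def grade_ratio_c_above(self) -> float:
        return self.raw["grading"]["ratio_c_above"]

    @property
    def smoking_grade_c_min_per_day(self) -> int:
        return self.raw["grading"]["smoking_grade_c_min_per_day"]

    @property
    def hba1c_grade_c_min_percent(self) -> float:
        return self.raw["grading"]["hba1c_grade_c_min_percent"]

    # -- extent ----------------------------------------------------------
    @property
    def generalized_min_fraction(self) -> float:
        return self.raw["extent"]["generalized_min_fraction"]

    # -- gingival status -------------------------------------------------
    @property
    def gingivitis_bop_min_fraction(self) -> float:
        return self.raw["gingival"]["gingivitis_bop_min_fraction"]

    @property
    def generalized_gingivitis_bop_fraction(self) -> float:
        return self.raw["gingival"]["generalized_gingivitis_bop_fraction"]

    # -- secondary findings ----------------------------------------------
    @property
    def secondary(self) -> dict[str, Any]:
        return self.raw["secondary"]

    def config_hash(self) -> str:
        """Stable short hash of the constant document (reproducibility log)."""
        blob = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> ClinicalConfig:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return ClinicalConfig(raw=raw, version=raw.get("version", "unversioned"))


def default_config() -> ClinicalConfig:
    """The packaged 2017-workshop constant set."""
    text = resources.files("periodx.data").joinpath("clinical_constants.json").read_text()
    raw = json.loads(text)
    return ClinicalConfig(raw=raw, version=raw.get("version", "unversioned"))
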