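"""Domain types for full-mouth periodontal charting, file I/O and summaries.

A chart records six probing sites per tooth (mesio-buccal, buccal,
disto-buccal, mesio-lingual, lingual, disto-lingual) with probing depth (PD)
and gingival recession in whole millimetres, bleeding on probing (BOP) and
suppuration, plus tooth-level radiographic bone loss, furcation and mobility
classes and a set of clinical flags. Clinical attachment loss (CAL) is
derived as PD + recession, with recession signed positive when the gingival
margin sits apical to the cemento-enamel junction and negative when coronal
to it.

Tooth numbering is the Universal system (1-16 maxilla, 17-32 mandible);
two teeth are adjacent only when consecutively numbered within one arch,
so teeth 16 and 17 are *not* adjacent.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

SITE_IDS = ("MB", "B", "DB", "ML", "L", "DL")
INTERPROXIMAL_SITES = frozenset({"MB", "DB", "ML", "DL"})
BUCCAL_LINGUAL_SITES = frozenset({"B", "L"})

TOOTH_FLAGS = frozenset(
    {
        "defective_restoration",
        "subgingival_margin",
        "enamel_projection",
        "root_proximity",
        "endodontic_involvement",
        "abscess",
        "fremitus",
        "widened_pdl",
        "progressive_bone_loss",
        "vertical_defect",
        "keratinized_tissue_deficiency",
    }
)

# Universal numbering anatomy groups.
MOLARS = frozenset({1, 2, 3, 14, 15, 16, 17, 18, 19, 30, 31, 32})
FIRST_SECOND_MOLARS = frozenset({2, 3, 14, 15, 18, 19, 30, 31})
MAXILLARY_FIRST_PREMOLARS = frozenset({5, 12})
INCISORS = frozenset({7, 8, 9, 10, 23, 24, 25, 26})
MULTIROOTED = MOLARS | MAXILLARY_FIRST_PREMOLARS


class ChartError(ValueError):
    """Raised on any chart/profile validation failure, with location info."""


def teeth_adjacent(a: int, b: int) -> bool:
    """Adjacency in the Universal system: consecutive numbers in one arch."""
    same_arch = (a <= 16) == (b <= 16)
    return same_arch and abs(a - b) == 1


@dataclass(frozen=True)
class SiteMeasurement:
    site_id: str
    probing_depth_mm: int
    recession_mm: int = 0
    bleeding_on_probing: bool = False
    suppuration: bool = False

    def __post_init__(self) -> None:
        if self.site_id not in SITE_IDS:
            raise ChartError(f"unknown site id {self.site_id!r}; expected one of {SITE_IDS}")
        if not isinstance(self.probing_depth_mm, int) or not 0 <= self.probing_depth_mm <= 20:
            raise ChartError(
                f"site {self.site_id}: probing depth {self.probing_depth_mm!r} outside 0-20 mm"
            )
        if not isinstance(self.recession_mm, int) or not -5 <= self.recession_mm <= 15:
            raise ChartError(
                f"site {self.site_id}: recession {self.recession_mm!r} outside -5..15 mm"
            )


def compute_cal(site: SiteMeasurement) -> int:
    """Clinical attachment loss in mm: probing depth plus signed recession."""
    return site.probing_depth_mm + site.recession_mm


@dataclass(frozen=True)
class ToothRecord:
    tooth_number: int
    present: bool = True
    is_implant: bool = False
    sites: tuple[SiteMeasurement, ...] = ()
    bone_loss_percent: float | None = None
    furcation_class: int = 0
    mobility_class: int = 0
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        t = self.tooth_number
        if not 1 <= t <= 32:
            raise ChartError(f"tooth number {t} outside Universal range 1-32")
        object.__setattr__(self, "sites", tuple(self.sites))
        object.__setattr__(self, "flags", frozenset(self.flags))
        where = f"tooth {t}"
        if not self.present:
            if self.sites:
                raise ChartError(f"{where}: missing tooth must carry no site measurements")
        else:
            ids = [s.site_id for s in self.sites]
            if len(set(ids)) != len(ids):
                raise ChartError(f"{where}: duplicate site ids {ids}")
            if self.is_implant:
                if not 4 <= len(self.sites) <= 6:
                    raise ChartError(f"{where}: implant requires 4-6 sites, got {len(self.sites)}")
            elif not 1 <= len(self.sites) <= 6:
                raise ChartError(f"{where}: tooth requires 1-6 measured sites, got {len(self.sites)}")
        if self.bone_loss_percent is not None and not 0 <= self.bone_loss_percent <= 100:
            raise ChartError(f"{where}: bone loss {self.bone_loss_percent}% outside 0-100")
        if not 0 <= self.furcation_class <= 3:
            raise ChartError(f"{where}: furcation class {self.furcation_class} outside 0-3")
        if self.furcation_class > 0 and t not in MULTIROOTED and not self.is_implant:
            raise ChartError(f"{where}: furcation involvement on a single-rooted tooth")
        if not 0 <= self.mobility_class <= 3:
            raise ChartError(f"{where}: mobility class {self.mobility_class} outside 0-3")
        unknown = self.flags - TOOTH_FLAGS
        if unknown:
            raise ChartError(f"{where}: unknown flags {sorted(unknown)}")

    def site(self, site_id: str) -> SiteMeasurement | None:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        return None


@dataclass(frozen=True)
class PatientProfile:
    age_years: int
    smoking_cigarettes_per_day: int = 0
    has_diabetes: bool = False
    hba1c_percent: float | None = None
    systemic_disease_codes: frozenset[str] = frozenset()
    teeth_lost_to_periodontitis: int = 0
    history_of_periodontal_treatment: bool = False
    masticatory_dysfunction: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "systemic_disease_codes", frozenset(self.systemic_disease_codes))
        if self.age_years <= 0:
            raise ChartError(f"age {self.age_years} must be positive")
        if self.smoking_cigarettes_per_day < 0:
            raise ChartError("cigarettes/day cannot be negative")
        if self.hba1c_percent is not None:
            if self.hba1c_percent < 0:
                raise ChartError("HbA1c cannot be negative")
            if not self.has_diabetes:
                raise ChartError("HbA1c recorded without a diabetes context")
        if self.teeth_lost_to_periodontitis < 0:
            raise ChartError("teeth lost to periodontitis cannot be negative")


@dataclass(frozen=True)
class PeriodontalChart:
    chart_id: str
    profile: PatientProfile
    teeth: Mapping[int, ToothRecord]
    exam_date: str = "1970-01-01"

    def __post_init__(self) -> None:
        object.__setattr__(self, "teeth", dict(self.teeth))
        if set(self.teeth) != set(range(1, 33)):
            missing = sorted(set(range(1, 33)) - set(self.teeth))
            extra = sorted(set(self.teeth) - set(range(1, 33)))
            raise ChartError(
                f"chart {self.chart_id}: need exactly one record per tooth 1-32 "
                f"(missing {missing}, unexpected {extra})"
            )
        for n, rec in self.teeth.items():
            if rec.tooth_number != n:
                raise ChartError(f"chart {self.chart_id}: tooth keyed {n} records number {rec.tooth_number}")
        n_missing = sum(1 for r in self.teeth.values() if not r.present)
        if self.profile.teeth_lost_to_periodontitis > n_missing:
            raise ChartError(
                f"chart {self.chart_id}: {self.profile.teeth_lost_to_periodontitis} teeth lost to "
                f"periodontitis exceeds {n_missing} missing teeth"
            )

    # -- convenience views ----------------------------------------------
    def present_natural_teeth(self) -> list[ToothRecord]:
        return [r for r in self.teeth.values() if r.present and not r.is_implant]

    def implants(self) -> list[ToothRecord]:
        return [r for r in self.teeth.values() if r.present and r.is_implant]

    def is_diagnosable(self) -> bool:
        return any(r.present for r in self.teeth.values())


@dataclass(frozen=True)
class ImplantSummary:
    tooth_number: int
    any_bop: bool
    any_suppuration: bool
    progressive_bone_loss: bool


@dataclass(frozen=True)
class ChartSummary:
    """Tooth-and-site aggregates that drive classification.

    Maxima are taken over present natural teeth only; interdental means the
    four interproximal sites, buccal/lingual the two mid-facial sites.
    ``affected_teeth`` are present natural teeth with at least one
    interproximal site of CAL >= 1 mm (the case-defining severity level);
    ``bleeding_site_fraction`` is bleeding sites over probed sites of
    natural teeth.
    """

    max_interdental_cal_mm: int
    max_cal_mm_buccal_lingual: int
    max_probing_depth_mm: int
    bleeding_site_fraction: float
    affected_teeth: frozenset[int]
    scorable_teeth_count: int
    worst_bone_loss_percent: float | None
    max_furcation_class: int
    has_vertical_defect: bool
    any_cal_or_bone_loss: bool
    buccal_lingual_case_teeth: frozenset[int]
    implant_summaries: tuple[ImplantSummary, ...] = ()


def summarize(chart: PeriodontalChart, interdental_cal_case_mm: int = 1,
              buccal_lingual_cal_case_mm: int = 3) -> ChartSummary:
    """Aggregate a chart into the quantities the classification rules read.

    Raises ChartError on a chart with no present teeth or implants.
    Unmeasured sites simply do not contribute to maxima or to the bleeding
    denominator.
    """
    if not chart.is_diagnosable():
        raise ChartError(f"chart {chart.chart_id}: no present teeth or implants to summarize")

    natural = chart.present_natural_teeth()
    max_id_cal = 0
    max_bl_cal = 0
    max_pd = 0
    bop = probed = 0
    affected: set[int] = set()
    bl_case: set[int] = set()
    worst_bl: float | None = None
    max_furc = 0
    vertical = False
    any_loss = False

    for rec in natural:
        for s in rec.sites:
            cal = compute_cal(s)
            probed += 1
            if s.bleeding_on_probing:
                bop += 1
            max_pd = max(max_pd, s.probing_depth_mm)
            if cal > 0:
                any_loss = True
            if s.site_id in INTERPROXIMAL_SITES:
                max_id_cal = max(max_id_cal, cal)
                if cal >= interdental_cal_case_mm:
                    affected.add(rec.tooth_number)
            else:
                max_bl_cal = max(max_bl_cal, cal)
                if cal >= buccal_lingual_cal_case_mm:
                    bl_case.add(rec.tooth_number)
        if rec.bone_loss_percent is not None:
            if rec.bone_loss_percent > 0:
                any_loss = True
            worst_bl = rec.bone_loss_percent if worst_bl is None else max(worst_bl, rec.bone_loss_percent)
        max_furc = max(max_furc, rec.furcation_class)
        if "vertical_defect" in rec.flags:
            vertical = True

    implant_summaries = tuple(
        ImplantSummary(
            tooth_number=rec.tooth_number,
            any_bop=any(s.bleeding_on_probing for s in rec.sites),
            any_suppuration=any(s.suppuration for s in rec.sites),
            progressive_bone_loss="progressive_bone_loss" in rec.flags,
        )
        for rec in sorted(chart.implants(), key=lambda r: r.tooth_number)
    )

    return ChartSummary(
        max_interdental_cal_mm=max_id_cal,
        max_cal_mm_buccal_lingual=max_bl_cal,
        max_probing_depth_mm=max_pd,
        bleeding_site_fraction=(bop / probed) if probed else 0.0,
        affected_teeth=frozenset(affected),
        scorable_teeth_count=len(natural),
        worst_bone_loss_percent=worst_bl,
        max_furcation_class=max_furc,
        has_vertical_defect=vertical,
        any_cal_or_bone_loss=any_loss or chart.profile.teeth_lost_to_periodontitis > 0,
        buccal_lingual_case_teeth=frozenset(bl_case),
        implant_summaries=implant_summaries,
    )


# ---------------------------------------------------------------------------
# JSON dialect
# ---------------------------------------------------------------------------

_PROFILE_FIELDS = {
    "age_years",
    "smoking_cigarettes_per_day",
    "has_diabetes",
    "hba1c_percent",
    "systemic_disease_codes",
    "teeth_lost_to_periodontitis",
    "history_of_periodontal_treatment",
    "masticatory_dysfunction",
}
_TOOTH_FIELDS = {
    "tooth_number", "present", "is_implant", "bone_loss_percent",
    "furcation_class", "mobility_class", "flags", "sites",
}
_SITE_FIELDS = {"site", "pd", "rec", "bop", "sup"}
_TOP_FIELDS = {"chart_id", "exam_date", "profile", "teeth"}


def _reject_unknown(obj: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise ChartError(f"{where}: unknown fields {sorted(unknown)}")


def chart_to_dict(chart: PeriodontalChart) -> dict:
    """Canonical JSON-dialect mapping (stable key order, sorted teeth)."""
    return {
        "chart_id": chart.chart_id,
        "exam_date": chart.exam_date,
        "profile": {
            "age_years": chart.profile.age_years,
            "smoking_cigarettes_per_day": chart.profile.smoking_cigarettes_per_day,
            "has_diabetes": chart.profile.has_diabetes,
            "hba1c_percent": chart.profile.hba1c_percent,
            "systemic_disease_codes": sorted(chart.profile.systemic_disease_codes),
            "teeth_lost_to_periodontitis": chart.profile.teeth_lost_to_periodontitis,
            "history_of_periodontal_treatment": chart.profile.history_of_periodontal_treatment,
            "masticatory_dysfunction": chart.profile.masticatory_dysfunction,
        },
        "teeth": [
            {
                "tooth_number": rec.tooth_number,
                "present": rec.present,
                "is_implant": rec.is_implant,
                "bone_loss_percent": rec.bone_loss_percent,
                "furcation_class": rec.furcation_class,
                "mobility_class": rec.mobility_class,
                "flags": sorted(rec.flags),
                "sites": [
                    {
                        "site": s.site_id,
                        "pd": s.probing_depth_mm,
                        "rec": s.recession_mm,
                        "bop": s.bleeding_on_probing,
                        "sup": s.suppuration,
                    }
                    for s in rec.sites
                ],
            }
            for rec in (chart.teeth[n] for n in sorted(chart.teeth))
        ],
    }


def chart_from_dict(doc: Mapping) -> PeriodontalChart:
    _reject_unknown(doc, _TOP_FIELDS, "chart")
    for key in ("chart_id", "profile", "teeth"):
        if key not in doc:
            raise ChartError(f"chart: missing required field {key!r}")
    pdoc = doc["profile"]
    _reject_unknown(pdoc, _PROFILE_FIELDS, "profile")
    profile = PatientProfile(
        age_years=pdoc["age_years"],
        smoking_cigarettes_per_day=pdoc.get("smoking_cigarettes_per_day", 0),
        has_diabetes=pdoc.get("has_diabetes", False),
        hba1c_percent=pdoc.get("hba1c_percent"),
        systemic_disease_codes=frozenset(pdoc.get("systemic_disease_codes", ())),
        teeth_lost_to_periodontitis=pdoc.get("teeth_lost_to_periodontitis", 0),
        history_of_periodontal_treatment=pdoc.get("history_of_periodontal_treatment", False),
        masticatory_dysfunction=pdoc.get("masticatory_dysfunction", False),
    )
    teeth: dict[int, ToothRecord] = {}
    for tdoc in doc["teeth"]:
        _reject_unknown(tdoc, _TOOTH_FIELDS, f"tooth {tdoc.get('tooth_number', '?')}")
        n = tdoc["tooth_number"]
        if n in teeth:
            raise ChartError(f"chart {doc['chart_id']}: tooth {n} listed twice")
        sites = []
        for i, sdoc in enumerate(tdoc.get("sites", ())):
            _reject_unknown(sdoc, _SITE_FIELDS, f"tooth {n} site #{i}")
            sites.append(
                SiteMeasurement(
                    site_id=sdoc["site"],
                    probing_depth_mm=sdoc["pd"],
                    recession_mm=sdoc.get("rec", 0),
                    bleeding_on_probing=bool(sdoc.get("bop", False)),
                    suppuration=bool(sdoc.get("sup", False)),
                )
            )
        teeth[n] = ToothRecord(
            tooth_number=n,
            present=tdoc.get("present", True),
            is_implant=tdoc.get("is_implant", False),
            sites=tuple(sites),
            bone_loss_percent=tdoc.get("bone_loss_percent"),
            furcation_class=tdoc.get("furcation_class", 0),
            mobility_class=tdoc.get("mobility_class", 0),
            flags=frozenset(tdoc.get("flags", ())),
        )
    return PeriodontalChart(
        chart_id=doc["chart_id"],
        profile=profile,
        teeth=teeth,
        exam_date=doc.get("exam_date", "1970-01-01"),
    )


# ---------------------------------------------------------------------------
# CSV dialect: one row per site plus one row per tooth plus profile rows,
# distinguished by a record_type column. UTF-8, header required.
# ---------------------------------------------------------------------------

CSV_COLUMNS = [
    "chart_id", "record_type", "tooth", "site", "pd", "rec", "bop", "sup",
    "present", "is_implant", "bone_loss", "furcation", "mobility", "flags",
    "field", "value",
]


def chart_to_csv(chart: PeriodontalChart, path: str | Path) -> None:
    doc = chart_to_dict(chart)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        w.writeheader()
        for key, value in doc["profile"].items():
            if key == "systemic_disease_codes":
                value = ";".join(value)
            w.writerow({"chart_id": chart.chart_id, "record_type": "profile",
                        "field": key, "value": "" if value is None else value})
        w.writerow({"chart_id": chart.chart_id, "record_type": "chart",
                    "field": "exam_date", "value": chart.exam_date})
        for tdoc in doc["teeth"]:
            w.writerow({
                "chart_id": chart.chart_id, "record_type": "tooth",
                "tooth": tdoc["tooth_number"], "present": int(tdoc["present"]),
                "is_implant": int(tdoc["is_implant"]),
                "bone_loss": "" if tdoc["bone_loss_percent"] is None else tdoc["bone_loss_percent"],
                "furcation": tdoc["furcation_class"], "mobility": tdoc["mobility_class"],
                "flags": ";".join(tdoc["flags"]),
            })
            for sdoc in tdoc["sites"]:
                w.writerow({
                    "chart_id": chart.chart_id, "record_type": "site",
                    "tooth": tdoc["tooth_number"], "site": sdoc["site"],
                    "pd": sdoc["pd"], "rec": sdoc["rec"],
                    "bop": int(sdoc["bop"]), "sup": int(sdoc["sup"]),
                })


def _csv_bool(v: str) -> bool:
    return v.strip().lower() in {"1", "true", "yes", "y"}


def chart_from_csv(path: str | Path) -> PeriodontalChart:
    profile_fields: dict[str, object] = {}
    exam_date = "1970-01-01"
    chart_id = None
    tooth_rows: dict[int, dict] = {}
    site_rows: dict[int, list[dict]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ChartError(f"{path}: empty CSV, header required")
        unknown = set(reader.fieldnames) - set(CSV_COLUMNS)
        if unknown:
            raise ChartError(f"{path}: unknown columns {sorted(unknown)}")
        for lineno, row in enumerate(reader, start=2):
            chart_id = chart_id or row["chart_id"]
            kind = row["record_type"]
            where = f"{path} line {lineno}"
            if kind == "profile":
                profile_fields[row["field"]] = row["value"]
            elif kind == "chart":
                if row["field"] == "exam_date":
                    exam_date = row["value"]
            elif kind == "tooth":
                n = int(row["tooth"])
                if n in tooth_rows:
                    raise ChartError(f"{where}: tooth {n} listed twice")
                tooth_rows[n] = row
            elif kind == "site":
                n = int(row["tooth"])
                if row["site"] not in SITE_IDS:
                    raise ChartError(f"{where}: unknown site {row['site']!r} on tooth {n}")
                site_rows.setdefault(n, []).append(row)
            else:
                raise ChartError(f"{where}: unknown record_type {kind!r}")
    if chart_id is None:
        raise ChartError(f"{path}: no data rows")

    def _pf(name: str, conv, default):
        v = profile_fields.get(name, "")
        return conv(v) if v not in ("", None) else default

    profile = PatientProfile(
        age_years=_pf("age_years", int, 0),
        smoking_cigarettes_per_day=_pf("smoking_cigarettes_per_day", int, 0),
        has_diabetes=_pf("has_diabetes", _csv_bool, False),
        hba1c_percent=_pf("hba1c_percent", float, None),
        systemic_disease_codes=frozenset(
            c for c in str(profile_fields.get("systemic_disease_codes", "")).split(";") if c
        ),
        teeth_lost_to_periodontitis=_pf("teeth_lost_to_periodontitis", int, 0),
        history_of_periodontal_treatment=_pf("history_of_periodontal_treatment", _csv_bool, False),
        masticatory_dysfunction=_pf("masticatory_dysfunction", _csv_bool, False),
    )
    teeth: dict[int, ToothRecord] = {}
    for n in range(1, 33):
        trow = tooth_rows.get(n)
        if trow is None:
            # teeth absent from the file are recorded as missing
            teeth[n] = ToothRecord(tooth_number=n, present=False)
            continue
        sites = tuple(
            SiteMeasurement(
                site_id=srow["site"],
                probing_depth_mm=int(srow["pd"]),
                recession_mm=int(srow["rec"] or 0),
                bleeding_on_probing=_csv_bool(srow["bop"] or ""),
                suppuration=_csv_bool(srow["sup"] or ""),
            )
            for srow in site_rows.get(n, ())
        )
        teeth[n] = ToothRecord(
            tooth_number=n,
            present=_csv_bool(trow["present"]),
            is_implant=_csv_bool(trow["is_implant"]),
            sites=sites,
            bone_loss_percent=float(trow["bone_loss"]) if trow["bone_loss"] else None,
            furcation_class=int(trow["furcation"] or 0),
            mobility_class=int(trow["mobility"] or 0),
            flags=frozenset(f for f in (trow["flags"] or "").split(";") if f),
        )
    return PeriodontalChart(chart_id=chart_id, profile=profile, teeth=teeth, exam_date=exam_date)


def load_chart(path: str | Path, dialect: str = "json") -> PeriodontalChart:
    """Load and fully validate a chart from the JSON or CSV dialect."""
    if dialect == "json":
        with open(path, encoding="utf-8") as fh:
            return chart_from_dict(json.load(fh))
    if dialect == "csv":
        return chart_from_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'json' or 'csv'")


def save_chart(chart: PeriodontalChart, path: str | Path, dialect: str = "json") -> None:
    if dialect == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(chart_to_dict(chart), fh, indent=1, sort_keys=True)
            fh.write("\n")
    elif dialect == "csv":
        chart_to_csv(chart, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
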