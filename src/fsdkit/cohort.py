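"""Respondent data model, cohort file I/O and the basic-demographics exclusion.

A cohort is a flat CSV/TSV table, one row per respondent, carrying
demographics, psychosocial covariates, the chronic-disease inventory and
the flattened item banks of five symptom instruments (WPI, ROME-III, CDC
symptom inventory, CIS fatigue, SCL-90 somatization at two waves).
Column names follow a canonical vocabulary; a schema config can remap
them for foreign files.

Missing-data policy is complete-case per analysis: loading never drops a
row silently — records carry their parse issues — and each downstream
analysis filters on the variables it actually uses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, DataError
from .scales import DURATION, FREQUENCY_CDC, FREQUENCY_ROME, HAMPER, SEVERITY_SCL

# ---------------------------------------------------------------------------
# Canonical vocabularies

#: Organ systems used for symptom clustering. fatigue_related is kept as a
#: fifth symptom system (fatigue and unrefreshing sleep do not sit naturally
#: in the four disease clusters); it can be collapsed into neurological_other
#: via the symptom catalog.
SYMPTOM_SYSTEMS = (
    "cardiorespiratory",
    "gastrointestinal",
    "musculoskeletal",
    "neurological_other",
    "fatigue_related",
)

#: Organ systems a chronic disease can be assigned to. "unassigned" marks
#: conditions (e.g. cancer) that do not belong to one system and are
#: excluded from same-system logic.
DISEASE_SYSTEMS = (
    "cardiorespiratory",
    "gastrointestinal",
    "musculoskeletal",
    "neurological_other",
    "unassigned",
)

#: The 19 WPI pain locations.
WPI_LOCATIONS = (
    "neck", "jaw_left", "jaw_right",
    "shoulder_left", "shoulder_right",
    "upper_arm_left", "upper_arm_right",
    "lower_arm_left", "lower_arm_right",
    "chest", "abdomen", "upper_back", "lower_back",
    "hip_left", "hip_right",
    "upper_leg_left", "upper_leg_right",
    "lower_leg_left", "lower_leg_right",
)

ROME_SYMPTOMS = (
    "loose_stools", "abdominal_pain", "bloating", "hard_stools",
    "constipation", "burning_upper_stomach", "postprandial_fullness",
    "early_satiety",
)

#: Boolean ROME items linking abdominal pain to defecation / stool change
#: (used by the IBS criteria, not by symptom qualification).
ROME_PAIN_ASSOCIATIONS = (
    "pain_defecation_related", "pain_stool_freq_change", "pain_stool_form_change",
)

CDC_ITEMS = (
    "muscle_pain", "joint_pain", "unrefreshing_sleep", "headache",
    "sore_throat", "tender_lymph_nodes", "memory_problems",
    "post_exertional_malaise",
)

SCL_SYMPTOMS = (
    "breathing_difficulty", "hot_cold_spells", "nausea",
    "localized_weakness", "numbness_tingling", "dizziness",
)

CIS_SCORE_MIN, CIS_SCORE_MAX = 8, 56

_DEMOGRAPHIC_COLUMNS = (
    "respondent_id", "age", "sex", "ethnicity", "education",
    "relationship_duration", "household_size", "work_hours",
    "providers_visited", "eq5d", "mini_depression", "mini_anxiety",
    "ctq", "lte", "ldi", "loneliness", "neuroticism", "chronic_diseases",
)


def canonical_columns() -> list[str]:
    """The full canonical column list, in write order."""
    cols = list(_DEMOGRAPHIC_COLUMNS)
    cols += [f"wpi_loc_{s}" for s in WPI_LOCATIONS]
    cols += ["wpi_duration", "wpi_hamper"]
    for sym in ROME_SYMPTOMS:
        cols += [f"rome_{sym}_{f}" for f in
                 ("duration", "frequency", "days_per_month", "hamper")]
    cols += [f"rome_{a}" for a in ROME_PAIN_ASSOCIATIONS]
    for item in CDC_ITEMS:
        cols += [f"cdc_{item}_frequency", f"cdc_{item}_duration"]
    cols += ["cis_score", "cis_persistent_6m"]
    cols += [f"scl1_{s}" for s in SCL_SYMPTOMS]
    cols += [f"scl2_{s}" for s in SCL_SYMPTOMS]
    cols += ["scl_gap_months"]
    return cols


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class RespondentRecord:
    """One participant's full instrument bank, demographics and covariates.

    Scalar fields are None when missing; the complete-case filters of the
    downstream analyses act on that. Item banks are dicts keyed by the
    canonical item names; ``scl_bank_t2`` is None when the second SCL wave
    was not observed (SCL symptoms then cannot qualify).
    """

    respondent_id: str
    age: Optional[int] = None
    sex: Optional[str] = None                # "male" / "female"
    ethnicity: Optional[str] = None          # "white_european" / "other"
    education: Optional[str] = None          # "low" / "medium" / "high"
    relationship_duration: Optional[float] = None
    household_size: Optional[int] = None
    work_hours: Optional[float] = None
    providers_visited: Optional[int] = None
    eq5d: Optional[float] = None             # 0..100
    mini_depression: Optional[bool] = None
    mini_anxiety: Optional[bool] = None
    ctq: Optional[float] = None
    lte: Optional[int] = None
    ldi: Optional[int] = None
    loneliness: Optional[float] = None
    neuroticism: Optional[float] = None
    chronic_diseases: set = field(default_factory=set)
    wpi_bank: dict = field(default_factory=dict)
    rome_bank: dict = field(default_factory=dict)
    cdc_bank: dict = field(default_factory=dict)
    cis_bank: dict = field(default_factory=dict)
    scl_bank_t1: Optional[dict] = None
    scl_bank_t2: Optional[dict] = None
    scl_gap_months: Optional[float] = None
    issues: list = field(default_factory=list)

    @property
    def demographics_missing(self) -> bool:
        return self.age is None or self.sex is None


class DiseaseCatalog:
    """Maps chronic-disease codes to the organ system they belong to.

    Codes mapped to "unassigned" (e.g. cancer) are excluded from the
    same-system specifier logic.
    """

    def __init__(self, mapping: Mapping[str, str]):
        for code, system in mapping.items():
            if system not in DISEASE_SYSTEMS:
                raise ConfigError(
                    f"disease {code!r} mapped to unknown system {system!r}"
                )
        self._mapping = dict(mapping)

    def system_of(self, code: str) -> Optional[str]:
        """Organ system for a code, or None if the code is unknown."""
        return self._mapping.get(code)

    def codes(self) -> set:
        return set(self._mapping)

    @classmethod
    def default(cls) -> "DiseaseCatalog":
        return cls(DEFAULT_DISEASE_MAPPING)

    @classmethod
    def from_file(cls, path) -> "DiseaseCatalog":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "diseases" not in data:
            raise ConfigError(f"{path}: expected a mapping with a 'diseases' key")
        return cls(data["diseases"])


#: Default chronic-disease catalog. The study matched self-reported
#: conditions to the symptom clusters' organ systems; this default covers
#: common self-report inventory conditions and is fully replaceable by
#: config.
DEFAULT_DISEASE_MAPPING = {
    "asthma": "cardiorespiratory",
    "copd": "cardiorespiratory",
    "heart_failure": "cardiorespiratory",
    "coronary_disease": "cardiorespiratory",
    "arrhythmia": "cardiorespiratory",
    "hypertension": "cardiorespiratory",
    "crohns_disease": "gastrointestinal",
    "ulcerative_colitis": "gastrointestinal",
    "stomach_ulcer": "gastrointestinal",
    "celiac_disease": "gastrointestinal",
    "liver_disease": "gastrointestinal",
    "rheumatoid_arthritis": "musculoskeletal",
    "osteoarthritis": "musculoskeletal",
    "osteoporosis": "musculoskeletal",
    "ankylosing_spondylitis": "musculoskeletal",
    "migraine": "neurological_other",
    "epilepsy": "neurological_other",
    "multiple_sclerosis": "neurological_other",
    "diabetes": "neurological_other",
    "thyroid_disorder": "neurological_other",
    "cancer": "unassigned",
}


# ---------------------------------------------------------------------------
# Schema

_DEFAULT_REQUIRED = ("respondent_id",)


class CohortSchema:
    """Column-mapping config for foreign cohort files.

    ``columns`` maps canonical names to the file's column names (identity
    for names not listed); ``required`` lists canonical columns that must
    be present in the file.
    """

    def __init__(self, columns: Optional[Mapping[str, str]] = None,
                 required: Optional[Sequence[str]] = None):
        self.columns = dict(columns or {})
        self.required = tuple(required if required is not None else _DEFAULT_REQUIRED)

    def source_column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_file(cls, path) -> "CohortSchema":
        path = Path(path)
        with open(path) as fh:
            data = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
        data = data or {}
        return cls(columns=data.get("columns"), required=data.get("required"))


# ---------------------------------------------------------------------------
# Parsing helpers

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and pd.isna(value)) or \
        (isinstance(value, str) and value.strip() == "")


def _parse_bool(value, field_name, issues):
    if _missing(value):
        return None
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    issues.append(f"{field_name}: unparseable boolean {value!r}")
    return None


def _parse_number(value, field_name, issues, *, as_int=False):
    if _missing(value):
        return None
    try:
        x = float(value)
    except (TypeError, ValueError):
        issues.append(f"{field_name}: unparseable number {value!r}")
        return None
    return int(round(x)) if as_int else x


def _parse_level(value, scale, field_name, issues):
    if _missing(value):
        return None
    s = str(value).strip()
    if s in scale:
        return s
    issues.append(f"{field_name}: {value!r} not on scale {scale.name}")
    return None


def _parse_enum(value, allowed, field_name, issues):
    if _missing(value):
        return None
    s = str(value).strip().lower()
    if s in allowed:
        return s
    issues.append(f"{field_name}: unexpected value {value!r}")
    return None


# ---------------------------------------------------------------------------
# Loading

def _row_to_record(row: Mapping, columns_present: set, schema: CohortSchema) -> RespondentRecord:
    issues: list[str] = []

    def get(canonical):
        col = schema.source_column(canonical)
        if col not in columns_present:
            return None
        return row.get(col)

    rec = RespondentRecord(respondent_id=str(get("respondent_id")).strip())
    rec.issues = issues

    rec.age = _parse_number(get("age"), "age", issues, as_int=True)
    rec.sex = _parse_enum(get("sex"), {"male", "female"}, "sex", issues)
    rec.ethnicity = _parse_enum(get("ethnicity"), {"white_european", "other"},
                                "ethnicity", issues)
    rec.education = _parse_enum(get("education"), {"low", "medium", "high"},
                                "education", issues)
    rec.relationship_duration = _parse_number(get("relationship_duration"),
                                              "relationship_duration", issues)
    rec.household_size = _parse_number(get("household_size"), "household_size",
                                       issues, as_int=True)
    rec.work_hours = _parse_number(get("work_hours"), "work_hours", issues)
    rec.providers_visited = _parse_number(get("providers_visited"),
                                          "providers_visited", issues, as_int=True)
    rec.eq5d = _parse_number(get("eq5d"), "eq5d", issues)
    rec.mini_depression = _parse_bool(get("mini_depression"), "mini_depression", issues)
    rec.mini_anxiety = _parse_bool(get("mini_anxiety"), "mini_anxiety", issues)
    rec.ctq = _parse_number(get("ctq"), "ctq", issues)
    rec.lte = _parse_number(get("lte"), "lte", issues, as_int=True)
    rec.ldi = _parse_number(get("ldi"), "ldi", issues, as_int=True)
    rec.loneliness = _parse_number(get("loneliness"), "loneliness", issues)
    rec.neuroticism = _parse_number(get("neuroticism"), "neuroticism", issues)

    for bounded, lo, hi in (("age", 18, 120), ("eq5d", 0, 100)):
        val = getattr(rec, bounded)
        if val is not None and not (lo <= val <= hi):
            issues.append(f"{bounded}: {val} outside [{lo}, {hi}]")
            setattr(rec, bounded, None)
    for count_field in ("household_size", "providers_visited", "lte", "ldi"):
        val = getattr(rec, count_field)
        if val is not None and val < 0:
            issues.append(f"{count_field}: negative count {val}")
            setattr(rec, count_field, None)

    diseases = get("chronic_diseases")
    if not _missing(diseases):
        rec.chronic_diseases = {c.strip() for c in str(diseases).split(";") if c.strip()}

    # WPI bank
    locations = {}
    for site in WPI_LOCATIONS:
        b = _parse_bool(get(f"wpi_loc_{site}"), f"wpi_loc_{site}", issues)
        if b is not None:
            locations[site] = b
    rec.wpi_bank = {
        "locations": locations,
        "duration": _parse_level(get("wpi_duration"), DURATION, "wpi_duration", issues),
        "hamper": _parse_level(get("wpi_hamper"), HAMPER, "wpi_hamper", issues),
    }

    # ROME bank
    rome: dict = {}
    for sym in ROME_SYMPTOMS:
        entry = {
            "duration": _parse_level(get(f"rome_{sym}_duration"), DURATION,
                                     f"rome_{sym}_duration", issues),
            "frequency": _parse_level(get(f"rome_{sym}_frequency"), FREQUENCY_ROME,
                                      f"rome_{sym}_frequency", issues),
            "days_per_month": _parse_number(get(f"rome_{sym}_days_per_month"),
                                            f"rome_{sym}_days_per_month", issues,
                                            as_int=True),
            "hamper": _parse_level(get(f"rome_{sym}_hamper"), HAMPER,
                                   f"rome_{sym}_hamper", issues),
        }
        if any(v is not None for v in entry.values()):
            rome[sym] = entry
    for assoc in ROME_PAIN_ASSOCIATIONS:
        b = _parse_bool(get(f"rome_{assoc}"), f"rome_{assoc}", issues)
        if b is not None:
            rome[assoc] = b
    rec.rome_bank = rome

    # CDC bank
    cdc: dict = {}
    for item in CDC_ITEMS:
        entry = {
            "frequency": _parse_level(get(f"cdc_{item}_frequency"), FREQUENCY_CDC,
                                      f"cdc_{item}_frequency", issues),
            "duration": _parse_level(get(f"cdc_{item}_duration"), DURATION,
                                     f"cdc_{item}_duration", issues),
        }
        if any(v is not None for v in entry.values()):
            cdc[item] = entry
    rec.cdc_bank = cdc

    # CIS bank
    score = _parse_number(get("cis_score"), "cis_score", issues, as_int=True)
    if score is not None and not (CIS_SCORE_MIN <= score <= CIS_SCORE_MAX):
        raise DataError(
            f"respondent {rec.respondent_id}: cis_score {score} outside "
            f"instrument range [{CIS_SCORE_MIN}, {CIS_SCORE_MAX}]"
        )
    persistent = _parse_bool(get("cis_persistent_6m"), "cis_persistent_6m", issues)
    rec.cis_bank = {}
    if score is not None or persistent is not None:
        rec.cis_bank = {"score": score, "persistent_6m": persistent}

    # SCL banks (two waves)
    for wave, attr in (("scl1", "scl_bank_t1"), ("scl2", "scl_bank_t2")):
        bank = {}
        for sym in SCL_SYMPTOMS:
            lvl = _parse_level(get(f"{wave}_{sym}"), SEVERITY_SCL,
                               f"{wave}_{sym}", issues)
            if lvl is not None:
                bank[sym] = lvl
        setattr(rec, attr, bank or None)
    rec.scl_gap_months = _parse_number(get("scl_gap_months"), "scl_gap_months", issues)

    return rec


def load_cohort(path, schema: Optional[CohortSchema] = None) -> list[RespondentRecord]:
    """Read a cohort CSV/TSV into RespondentRecords.

    Unparseable fields are recorded on each record's ``issues`` list, never
    silently dropped. Raises ConfigError when a required column is absent
    and DataError on duplicate respondent ids.
    """
    schema = schema or CohortSchema()
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".tab") else ","
    frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    columns_present = set(frame.columns)
    missing_required = [c for c in schema.required
                        if schema.source_column(c) not in columns_present]
    if missing_required:
        raise ConfigError(
            f"{path.name}: required column(s) missing: {', '.join(missing_required)}"
        )

    records = [_row_to_record(row, columns_present, schema)
               for row in frame.to_dict("records")]

    seen: dict[str, int] = {}
    dupes = []
    for rec in records:
        seen[rec.respondent_id] = seen.get(rec.respondent_id, 0) + 1
    dupes = sorted(rid for rid, n in seen.items() if n > 1)
    if dupes:
        raise DataError(f"duplicate respondent_id(s): {', '.join(dupes)}")
    return records


def _record_to_row(rec: RespondentRecord) -> dict:
    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return "1" if v else "0"
        if isinstance(v, float) and v == int(v):
            return str(int(v))
        return str(v)

    row = {c: "" for c in canonical_columns()}
    for name in _DEMOGRAPHIC_COLUMNS:
        if name == "chronic_diseases":
            row[name] = ";".join(sorted(rec.chronic_diseases))
        else:
            row[name] = fmt(getattr(rec, name))
    locs = rec.wpi_bank.get("locations", {}) if rec.wpi_bank else {}
    for site in WPI_LOCATIONS:
        row[f"wpi_loc_{site}"] = fmt(locs.get(site))
    if rec.wpi_bank:
        row["wpi_duration"] = fmt(rec.wpi_bank.get("duration"))
        row["wpi_hamper"] = fmt(rec.wpi_bank.get("hamper"))
    for sym in ROME_SYMPTOMS:
        entry = rec.rome_bank.get(sym, {})
        for f in ("duration", "frequency", "days_per_month", "hamper"):
            row[f"rome_{sym}_{f}"] = fmt(entry.get(f))
    for assoc in ROME_PAIN_ASSOCIATIONS:
        row[f"rome_{assoc}"] = fmt(rec.rome_bank.get(assoc))
    for item in CDC_ITEMS:
        entry = rec.cdc_bank.get(item, {})
        row[f"cdc_{item}_frequency"] = fmt(entry.get("frequency"))
        row[f"cdc_{item}_duration"] = fmt(entry.get("duration"))
    if rec.cis_bank:
        row["cis_score"] = fmt(rec.cis_bank.get("score"))
        row["cis_persistent_6m"] = fmt(rec.cis_bank.get("persistent_6m"))
    for wave, bank in (("scl1", rec.scl_bank_t1), ("scl2", rec.scl_bank_t2)):
        for sym in SCL_SYMPTOMS:
            row[f"{wave}_{sym}"] = fmt((bank or {}).get(sym))
    row["scl_gap_months"] = fmt(rec.scl_gap_months)
    return row


def save_cohort(records: Iterable[RespondentRecord], path) -> None:
    """Write records to CSV in canonical column order (round-trips load_cohort)."""
    rows = [_record_to_row(r) for r in records]
    frame = pd.DataFrame(rows, columns=canonical_columns())
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Exclusions

def apply_exclusions(records: Sequence[RespondentRecord],
                     required_fields: Sequence[str] = ("age", "sex"),
                     ) -> tuple[list[RespondentRecord], list[tuple[RespondentRecord, str]]]:
    """Partition records into (included, excluded-with-reason).

    Respondents lacking basic demographic data — by default age or sex —
    are excluded; the required field list is configurable.
    """
    included, excluded = [], []
    for rec in records:
        missing = [f for f in required_fields if getattr(rec, f) is None]
        if missing:
            excluded.append((rec, "basic demographics missing: " + ", ".join(missing)))
        else:
            included.append(rec)
    return included, excluded


def records_to_frame(records: Sequence[RespondentRecord]) -> pd.DataFrame:
    """Covariate view of a cohort as a typed DataFrame (one row per respondent)."""
    cols = [c for c in _DEMOGRAPHIC_COLUMNS if c != "chronic_diseases"]
    data = {c: [getattr(r, c) for r in records] for c in cols}
    frame = pd.DataFrame(data)
    frame["chronic_diseases"] = [sorted(r.chronic_diseases) for r in records]
    return frame
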