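"""Optional FSD specifiers: same-system chronic disease, concurrent
psychiatric diagnoses, and the three specialty-specific functional
syndromes (chronic fatigue syndrome, fibromyalgia, irritable bowel
syndrome).

Syndrome criteria are declarative predicate sets over instrument fields,
evaluated in three-valued logic: True, False, or None ("undetermined",
when a required instrument bank is missing). The shipped defaults
approximate CDC-1994 CFS, ACR-2010/FSQ fibromyalgia and ROME-III IBS;
every threshold is config-replaceable, and correctness is defined
against the configured criteria, not against any external dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from .classify import FsdClassification
from .cohort import DiseaseCatalog, RespondentRecord, ROME_PAIN_ASSOCIATIONS
from .errors import ConfigError, DataError
from .scales import DURATION, FREQUENCY_CDC, FREQUENCY_ROME, HAMPER, SEVERITY_SCL

log = logging.getLogger(__name__)

SYNDROMES = ("cfs", "fibromyalgia", "ibs")

#: Disease systems eligible for the same-system flag (fatigue_related has
#: no disease cluster).
SAME_SYSTEM_FLAGS = ("cardiorespiratory", "gastrointestinal",
                     "musculoskeletal", "neurological_other")


@dataclass
class SpecifierProfile:
    respondent_id: str
    same_system_disease: dict = field(default_factory=dict)
    any_same_system: bool = False
    concurrent_depression: Optional[bool] = None
    concurrent_anxiety: Optional[bool] = None
    cfs: Optional[bool] = None           # None = undetermined (bank missing)
    fibromyalgia: Optional[bool] = None
    ibs: Optional[bool] = None
    undetermined: list = field(default_factory=list)

    @property
    def n_syndromes(self) -> int:
        return sum(bool(getattr(self, s)) for s in SYNDROMES)


# ---------------------------------------------------------------------------
# Same-system chronic disease

def same_system_disease(record: RespondentRecord,
                        classification: FsdClassification,
                        catalog: DiseaseCatalog,
                        strict: bool = False) -> dict:
    """Per-system flags: the respondent has a chronic disease from an
    organ system that also contains one of their qualifying symptoms.

    Diseases mapped to "unassigned" are ignored; unknown codes warn (or
    raise in strict mode).
    """
    disease_systems = set()
    for code in sorted(record.chronic_diseases):
        system = catalog.system_of(code)
        if system is None:
            if strict:
                raise DataError(f"respondent {record.respondent_id}: unknown "
                                f"disease code {code!r}")
            log.warning("respondent %s: unknown disease code %r ignored",
                        record.respondent_id, code)
        elif system != "unassigned":
            disease_systems.add(system)
    return {system: (system in classification.systems_involved
                     and system in disease_systems)
            for system in SAME_SYSTEM_FLAGS}


# ---------------------------------------------------------------------------
# Declarative syndrome criteria

_SCALE_BY_SUFFIX = {
    "hamper": HAMPER,
    "frequency_rome": FREQUENCY_ROME,
    "frequency_cdc": FREQUENCY_CDC,
    "severity_scl": SEVERITY_SCL,
    "duration": DURATION,
}

_MISSING_BANK = object()


def _field_value(record: RespondentRecord, name: str):
    """Resolve a dotted field name; _MISSING_BANK when the bank is absent."""
    parts = name.split(".")
    root = parts[0]
    if root == "cis":
        if not record.cis_bank:
            return _MISSING_BANK, None
        return record.cis_bank.get(parts[1]), None
    if root == "wpi":
        if not record.wpi_bank:
            return _MISSING_BANK, None
        if parts[1] == "n_locations":
            locs = record.wpi_bank.get("locations") or {}
            return sum(bool(v) for v in locs.values()), None
        scale = HAMPER if parts[1] == "hamper" else DURATION if parts[1] == "duration" else None
        return record.wpi_bank.get(parts[1]), scale
    if root == "cdc":
        if not record.cdc_bank:
            return _MISSING_BANK, None
        item, leaf = parts[1], parts[2]
        scale = FREQUENCY_CDC if leaf == "frequency" else DURATION
        return (record.cdc_bank.get(item) or {}).get(leaf), scale
    if root == "rome":
        if not record.rome_bank:
            return _MISSING_BANK, None
        if parts[1] in ROME_PAIN_ASSOCIATIONS:
            return record.rome_bank.get(parts[1]), None
        item, leaf = parts[1], parts[2]
        scale = {"frequency": FREQUENCY_ROME, "duration": DURATION,
                 "hamper": HAMPER}.get(leaf)
        return (record.rome_bank.get(item) or {}).get(leaf), scale
    if root in ("scl1", "scl2"):
        bank = record.scl_bank_t1 if root == "scl1" else record.scl_bank_t2
        if bank is None:
            return _MISSING_BANK, None
        return bank.get(parts[1]), SEVERITY_SCL
    raise ConfigError(f"unknown criteria field {name!r}")


def _eval_clause(record: RespondentRecord, clause: Mapping) -> Optional[bool]:
    """Evaluate one clause in three-valued logic (None = undetermined)."""
    if "at_least" in clause:
        k = clause["at_least"]
        verdicts = [_eval_clause(record, c) for c in clause["of"]]
        n_true = sum(v is True for v in verdicts)
        n_open = sum(v is None for v in verdicts)
        if n_true >= k:
            return True
        if n_true + n_open < k:
            return False
        return None
    if "all" in clause:
        verdicts = [_eval_clause(record, c) for c in clause["all"]]
        if any(v is False for v in verdicts):
            return False
        if any(v is None for v in verdicts):
            return None
        return True

    value, scale = _field_value(record, clause["field"])
    if value is _MISSING_BANK:
        return None
    op = clause["op"]
    if value is None:
        # Bank present but the item unanswered: the predicate fails.
        return False
    if op == "true":
        return bool(value)
    if op == "false":
        return not bool(value)
    target = clause["value"]
    if scale is not None and isinstance(target, str):
        lhs, rhs = scale.index(value), scale.index(target)
    else:
        lhs, rhs = value, target
    if op == "ge":
        return lhs >= rhs
    if op == "gt":
        return lhs > rhs
    if op == "le":
        return lhs <= rhs
    if op == "eq":
        return lhs == rhs
    raise ConfigError(f"unknown criteria op {op!r}")


#: Default syndrome criteria. Thresholds are documented approximations of
#: the cited diagnostic schemes, expressed over the fields this package's
#: instrument banks carry.
DEFAULT_SYNDROME_CRITERIA: dict = {
    # CDC-1994-style CFS: severe persistent fatigue plus accompanying
    # symptoms occurring at least monthly. The accompanying count is taken
    # over the four CDC inventory items that are not themselves candidate
    # FSD symptoms, so the syndrome axis stays separable from symptom
    # qualification.
    "cfs": {"all": [
        {"field": "cis.score", "op": "ge", "value": 35},
        {"field": "cis.persistent_6m", "op": "true"},
        {"at_least": 3, "of": [
            {"field": f"cdc.{item}.frequency", "op": "ge", "value": "monthly"}
            for item in ("sore_throat", "tender_lymph_nodes",
                         "memory_problems", "post_exertional_malaise")
        ]},
    ]},
    # ACR-2010/FSQ-style fibromyalgia: widespread pain (WPI >= 7 locations,
    # present at least 3 months) plus a symptom-severity composite
    # (2 of 3 severity markers).
    "fibromyalgia": {"all": [
        {"field": "wpi.n_locations", "op": "ge", "value": 7},
        {"field": "wpi.duration", "op": "ge", "value": "three_to_six_months"},
        {"at_least": 2, "of": [
            {"field": "cis.score", "op": "ge", "value": 35},
            {"field": "cdc.unrefreshing_sleep.frequency", "op": "ge",
             "value": "a_few_times_a_week"},
            {"field": "cdc.memory_problems.frequency", "op": "ge",
             "value": "a_few_times_a_week"},
        ]},
    ]},
    # ROME-III-style IBS: recurrent abdominal pain >= 3 days/month with
    # onset over 6 months ago, associated with >= 2 of the three
    # defecation/stool-change features.
    "ibs": {"all": [
        {"field": "rome.abdominal_pain.days_per_month", "op": "ge", "value": 3},
        {"field": "rome.abdominal_pain.duration", "op": "gt", "value": "six_months"},
        {"at_least": 2, "of": [
            {"field": "rome.pain_defecation_related", "op": "true"},
            {"field": "rome.pain_stool_freq_change", "op": "true"},
            {"field": "rome.pain_stool_form_change", "op": "true"},
        ]},
    ]},
}


def load_syndrome_criteria(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict) or set(data) != set(SYNDROMES):
        raise ConfigError(f"{path}: expected exactly the keys {SYNDROMES}")
    return data


def syndrome_criteria(record: RespondentRecord,
                      criteria: Optional[Mapping] = None,
                      ) -> tuple[Optional[bool], Optional[bool], Optional[bool]]:
    """Evaluate (cfs, fibromyalgia, ibs); None means undetermined because
    a required instrument bank is missing."""
    criteria = criteria or DEFAULT_SYNDROME_CRITERIA
    out = []
    for name in SYNDROMES:
        verdict = _eval_clause(record, criteria[name])
        if verdict is None:
            log.info("respondent %s: %s undetermined (instrument bank missing)",
                     record.respondent_id, name)
        out.append(verdict)
    return tuple(out)


# ---------------------------------------------------------------------------
# Profiles and summary tables

def build_profile(record: RespondentRecord,
                  classification: FsdClassification,
                  disease_catalog: Optional[DiseaseCatalog] = None,
                  criteria: Optional[Mapping] = None,
                  strict_diseases: bool = False) -> SpecifierProfile:
    disease_catalog = disease_catalog or DiseaseCatalog.default()
    flags = same_system_disease(record, classification, disease_catalog,
                                strict=strict_diseases)
    cfs, fm, ibs = syndrome_criteria(record, criteria)
    profile = SpecifierProfile(
        respondent_id=record.respondent_id,
        same_system_disease=flags,
        any_same_system=any(flags.values()),
        concurrent_depression=record.mini_depression,
        concurrent_anxiety=record.mini_anxiety,
        cfs=cfs, fibromyalgia=fm, ibs=ibs,
        undetermined=[s for s, v in zip(SYNDROMES, (cfs, fm, ibs)) if v is None],
    )
    return profile


def syndrome_count_table(classifications: Sequence[FsdClassification],
                         profiles: Sequence[SpecifierProfile]) -> pd.DataFrame:
    """Counts of FSD cases meeting 0/1/2/3 functional-syndrome criteria."""
    by_id = {p.respondent_id: p for p in profiles}
    counts = {k: 0 for k in range(4)}
    n_cases = 0
    for c in classifications:
        if not c.is_case:
            continue
        n_cases += 1
        counts[by_id[c.respondent_id].n_syndromes] += 1
    labels = ["no_syndrome", "one_syndrome", "two_syndromes", "all_three"]
    return pd.DataFrame({
        "n_syndromes": list(range(4)),
        "label": labels,
        "count": [counts[k] for k in range(4)],
        "percent": [round(100.0 * counts[k] / n_cases, 1) if n_cases else 0.0
                    for k in range(4)],
    })


def profiles_to_frame(profiles: Sequence[SpecifierProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"respondent_id": p.respondent_id,
               "any_same_system": p.any_same_system,
               "concurrent_depression": p.concurrent_depression,
               "concurrent_anxiety": p.concurrent_anxiety,
               "cfs": p.cfs, "fibromyalgia": p.fibromyalgia, "ibs": p.ibs,
               "n_syndromes": p.n_syndromes}
        row.update({f"same_system_{s}": p.same_system_disease.get(s, False)
                    for s in SAME_SYSTEM_FLAGS})
        rows.append(row)
    return pd.DataFrame(rows)
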