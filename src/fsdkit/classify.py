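"""FSD caseness and subgroup classification.

A respondent is an FSD case iff they have at least one qualifying
(persistent AND troublesome) symptom. Cases are sub-classified:

* single_symptom — exactly one qualifying symptom;
* single_system  — two or more qualifying symptoms, all from one organ
  system;
* multi_system   — qualifying symptoms from two or more organ systems.

The four labels (with non_case) partition any cohort. Symptoms are
counted by distinct symptom_id; a symptom that qualifies through two
instruments counts once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ContractViolation
from .symptoms import SymptomRecord

SUBGROUPS = ("non_case", "single_symptom", "single_system", "multi_system")


@dataclass(frozen=True)
class FsdClassification:
    respondent_id: str
    is_case: bool
    subgroup: str
    n_symptoms: int
    n_systems: int
    systems_involved: frozenset

    def __post_init__(self):
        assert self.subgroup in SUBGROUPS


def classify(symptoms: Sequence[SymptomRecord],
             respondent_id: str | None = None) -> FsdClassification:
    """Turn one respondent's qualifying symptoms into caseness + subgroup.

    All input records must qualify and share one respondent_id (pass
    ``respondent_id`` explicitly for the empty list).
    """
    ids = {s.respondent_id for s in symptoms}
    if len(ids) > 1:
        raise ContractViolation(f"symptoms from multiple respondents: {sorted(ids)}")
    if not all(s.qualifies for s in symptoms):
        raise ContractViolation("classify() requires qualifying symptoms only")
    if ids:
        rid = ids.pop()
        if respondent_id is not None and respondent_id != rid:
            raise ContractViolation(
                f"respondent_id {respondent_id!r} does not match records ({rid!r})")
        respondent_id = rid
    elif respondent_id is None:
        respondent_id = ""

    symptom_ids = {s.symptom_id for s in symptoms}
    systems = frozenset(s.organ_system for s in symptoms)
    n_symptoms, n_systems = len(symptom_ids), len(systems)

    if n_symptoms == 0:
        subgroup = "non_case"
    elif n_systems >= 2:
        subgroup = "multi_system"
    elif n_symptoms == 1:
        subgroup = "single_symptom"
    else:
        subgroup = "single_system"

    return FsdClassification(respondent_id, n_symptoms >= 1, subgroup,
                             n_symptoms, n_systems, systems)


def classify_cohort(symptoms_by_respondent: dict) -> list[FsdClassification]:
    """Classify every respondent given a mapping id -> qualifying symptoms."""
    return [classify(symp, respondent_id=rid)
            for rid, symp in symptoms_by_respondent.items()]


def tabulate_system_counts(classifications: Sequence[FsdClassification]) -> pd.DataFrame:
    """Distribution of organ-system counts among cases.

    Returns a frame with columns n_systems / count / percent (percent of
    cases, 1 d.p.); empty for a cohort with no cases.
    """
    cases = [c for c in classifications if c.is_case]
    if not cases:
        return pd.DataFrame(columns=["n_systems", "count", "percent"])
    counts = pd.Series([c.n_systems for c in cases]).value_counts().sort_index()
    return pd.DataFrame({
        "n_systems": counts.index.to_numpy(),
        "count": counts.to_numpy(),
        "percent": (100.0 * counts / len(cases)).round(1).to_numpy(),
    })


def classifications_to_frame(classifications: Sequence[FsdClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"respondent_id": c.respondent_id, "is_case": c.is_case,
          "subgroup": c.subgroup, "n_symptoms": c.n_symptoms,
          "n_systems": c.n_systems,
          "systems": ";".join(sorted(c.systems_involved))}
         for c in classifications],
        columns=["respondent_id", "is_case", "subgroup",
                 "n_symptoms", "n_systems", "systems"],
    )
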