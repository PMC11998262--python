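"""Symptom catalog: which symptoms exist, which instrument measures each,
and which organ system each belongs to.

The full symptom/system assignment used by the original study is not part
of the published text, so the catalog is config-driven with a documented
default assembled from the symptoms the instruments cover.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import yaml

from .cohort import SYMPTOM_SYSTEMS
from .errors import ConfigError

INSTRUMENTS = ("WPI", "ROME", "CDC", "CIS", "SCL")

#: ROME troublesomeness has two routes — a frequency rule (>= often on
#: >= 3 days/month) or a hamper rule (>= quite_a_bit) — applied per
#: symptom. Default: frequency for stool-pattern symptoms, hamper for
#: pain/bloating/dyspepsia symptoms.
ROME_MODES = ("frequency", "hamper")


@dataclass(frozen=True)
class SymptomDefinition:
    """One candidate symptom: its source instrument, organ system and
    any per-symptom rule parameters."""

    symptom_id: str
    display_name: str
    instrument: str
    organ_system: str
    rule_params: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if self.instrument not in INSTRUMENTS:
            raise ConfigError(f"{self.symptom_id}: unknown instrument "
                              f"{self.instrument!r}")
        if self.organ_system not in SYMPTOM_SYSTEMS:
            raise ConfigError(f"{self.symptom_id}: unknown organ system "
                              f"{self.organ_system!r}")


class SymptomCatalog:
    """An ordered, id-unique collection of SymptomDefinitions."""

    def __init__(self, definitions):
        self._defs = {}
        for d in definitions:
            if d.symptom_id in self._defs:
                raise ConfigError(f"duplicate symptom_id {d.symptom_id!r}")
            self._defs[d.symptom_id] = d

    def __iter__(self):
        return iter(self._defs.values())

    def __len__(self):
        return len(self._defs)

    def __contains__(self, symptom_id):
        return symptom_id in self._defs

    def get(self, symptom_id: str) -> SymptomDefinition:
        try:
            return self._defs[symptom_id]
        except KeyError:
            raise ConfigError(f"unknown symptom_id {symptom_id!r}") from None

    def by_instrument(self, instrument: str) -> list[SymptomDefinition]:
        return [d for d in self if d.instrument == instrument]

    def systems(self) -> set:
        return {d.organ_system for d in self}

    @classmethod
    def default(cls, collapse_fatigue: bool = False) -> "SymptomCatalog":
        """The documented default catalog.

        With ``collapse_fatigue=True`` the fatigue_related symptoms are
        reassigned to neurological_other, reducing the system count to
        the four disease clusters.
        """
        defs = [SymptomDefinition(**kw) for kw in _DEFAULT_CATALOG]
        if collapse_fatigue:
            defs = [
                SymptomDefinition(
                    d.symptom_id, d.display_name, d.instrument,
                    "neurological_other" if d.organ_system == "fatigue_related"
                    else d.organ_system,
                    d.rule_params,
                )
                for d in defs
            ]
        return cls(defs)

    @classmethod
    def from_file(cls, path) -> "SymptomCatalog":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict) or "symptoms" not in data:
            raise ConfigError(f"{path}: expected a mapping with a 'symptoms' key")
        defs = []
        for entry in data["symptoms"]:
            try:
                defs.append(SymptomDefinition(
                    symptom_id=entry["symptom_id"],
                    display_name=entry.get("display_name", entry["symptom_id"]),
                    instrument=entry["instrument"],
                    organ_system=entry["organ_system"],
                    rule_params=entry.get("rule_params", {}),
                ))
            except KeyError as exc:
                raise ConfigError(f"{path}: symptom entry missing key {exc}") from None
        return cls(defs)


def _rome(symptom_id, name, mode):
    return dict(symptom_id=symptom_id, display_name=name, instrument="ROME",
                organ_system="gastrointestinal", rule_params={"mode": mode})


def _cdc(symptom_id, name, system):
    return dict(symptom_id=symptom_id, display_name=name, instrument="CDC",
                organ_system=system)


def _scl(symptom_id, name, system):
    return dict(symptom_id=symptom_id, display_name=name, instrument="SCL",
                organ_system=system)


_DEFAULT_CATALOG = [
    # WPI: the duration and hamper questions are asked once about
    # "musculoskeletal pain complaints", so the default emits one
    # aggregate symptom (per-location emission is a config option).
    dict(symptom_id="musculoskeletal_pain", display_name="Musculoskeletal pain",
         instrument="WPI", organ_system="musculoskeletal"),
    _rome("loose_stools", "Frequent loose bowel movements", "frequency"),
    _rome("abdominal_pain", "Abdominal pain", "hamper"),
    _rome("bloating", "Feeling bloated", "hamper"),
    _rome("hard_stools", "Hard stools", "frequency"),
    _rome("constipation", "Constipation", "frequency"),
    _rome("burning_upper_stomach", "Burning sensation in upper stomach", "hamper"),
    _rome("postprandial_fullness", "Unpleasant bloating after meals", "hamper"),
    _rome("early_satiety", "Inability to complete meals", "hamper"),
    _cdc("muscle_pain", "Muscle pain", "musculoskeletal"),
    _cdc("joint_pain", "Joint pain", "musculoskeletal"),
    _cdc("unrefreshing_sleep", "Unrefreshing sleep", "fatigue_related"),
    _cdc("headache", "Headache", "neurological_other"),
    dict(symptom_id="fatigue", display_name="Severe fatigue",
         instrument="CIS", organ_system="fatigue_related"),
    _scl("breathing_difficulty", "Difficulty breathing", "cardiorespiratory"),
    _scl("hot_cold_spells", "Hot and cold spells", "cardiorespiratory"),
    _scl("nausea", "Nausea", "gastrointestinal"),
    _scl("localized_weakness", "Localised weakness", "neurological_other"),
    _scl("numbness_tingling", "Numbness or tingling", "neurological_other"),
    _scl("dizziness", "Dizziness", "neurological_other"),
]
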