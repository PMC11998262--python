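"""The five instrument-specific rules deciding whether a symptom is
persistent (>= 6 months) and troublesome (moderate-to-severe impact).

Each instrument phrases duration and impact on its own Likert scales, so
each has its own rule:

* WPI — musculoskeletal pain locations; duration "6 months or longer"
  (inclusive) and hamper >= quite_a_bit.
* ROME-III — eight gastrointestinal symptoms; duration longer than 6
  months (strict) and, per symptom, either frequency >= often on >= 3
  days/month or hamper >= quite_a_bit.
* CDC symptom inventory — frequency >= a_few_times_a_week for longer
  than 6 months.
* CIS — fatigue severity score at the recommended cut-off (>= 35) plus a
  6-month persistence flag.
* SCL-90 somatization — no duration item; persistence is moderate+
  severity at both of two waves (on average ~16 months apart).

A symptom qualifies iff it is persistent AND troublesome; that
equivalence is enforced in the SymptomRecord constructor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .catalog import SymptomCatalog, SymptomDefinition
from .cohort import ROME_SYMPTOMS, RespondentRecord, CIS_SCORE_MAX, CIS_SCORE_MIN
from .errors import ConfigError, DataError
from .scales import DURATION, FREQUENCY_CDC, FREQUENCY_ROME, HAMPER, SEVERITY_SCL

log = logging.getLogger(__name__)

CIS_FATIGUE_CUTOFF = 35


@dataclass(frozen=True)
class SymptomRecord:
    """One candidate symptom for one respondent, with the rule verdict."""

    respondent_id: str
    symptom_id: str
    organ_system: str
    persistent: bool
    troublesome: bool
    provenance: str

    @property
    def qualifies(self) -> bool:
        return self.persistent and self.troublesome


# ---------------------------------------------------------------------------
# Per-instrument rules

def qualify_wpi(record: RespondentRecord,
                definition: Optional[SymptomDefinition] = None,
                per_location: bool = False) -> list[SymptomRecord]:
    """WPI rule: pain at >= 1 location, for 6 months or longer (inclusive),
    hampering activities quite_a_bit or more.

    Default emits one aggregate musculoskeletal-pain record, because the
    duration and hamper questions are asked once about "musculoskeletal
    pain complaints"; ``per_location=True`` emits one record per reported
    location instead.
    """
    bank = record.wpi_bank or {}
    locations = [s for s, present in (bank.get("locations") or {}).items() if present]
    if not locations:
        return []

    duration = bank.get("duration")
    hamper = bank.get("hamper")
    if duration is None:
        log.warning("respondent %s: WPI pain reported without a duration answer; "
                    "treated as not persistent", record.respondent_id)
    persistent = duration is not None and DURATION.at_least(duration, "six_months")
    troublesome = hamper is not None and HAMPER.at_least(hamper, "quite_a_bit")

    system = definition.organ_system if definition else "musculoskeletal"
    base_id = definition.symptom_id if definition else "musculoskeletal_pain"
    if per_location:
        return [SymptomRecord(record.respondent_id, f"{base_id}__{site}", system,
                              persistent, troublesome, "WPI per-location rule")
                for site in sorted(locations)]
    return [SymptomRecord(record.respondent_id, base_id, system,
                          persistent, troublesome, "WPI aggregate rule")]


def qualify_rome(record: RespondentRecord,
                 definitions: Sequence[SymptomDefinition]) -> list[SymptomRecord]:
    """ROME-III rule: duration strictly over 6 months, and either the
    frequency route (>= often on >= 3 days/month) or the hamper route
    (>= quite_a_bit), chosen per symptom by its ``rule_params["mode"]``."""
    out = []
    bank = record.rome_bank or {}
    for d in definitions:
        if d.symptom_id not in ROME_SYMPTOMS:
            raise ConfigError(f"unknown ROME symptom id {d.symptom_id!r}")
        entry = bank.get(d.symptom_id)
        if not entry:
            continue
        duration = entry.get("duration")
        persistent = duration is not None and DURATION.above(duration, "six_months")
        mode = d.rule_params.get("mode", "hamper")
        if mode == "frequency":
            freq, days = entry.get("frequency"), entry.get("days_per_month")
            troublesome = (freq is not None and days is not None
                           and FREQUENCY_ROME.at_least(freq, "often") and days >= 3)
        elif mode == "hamper":
            hamper = entry.get("hamper")
            troublesome = hamper is not None and HAMPER.at_least(hamper, "quite_a_bit")
        else:
            raise ConfigError(f"{d.symptom_id}: unknown ROME mode {mode!r}")
        out.append(SymptomRecord(record.respondent_id, d.symptom_id, d.organ_system,
                                 persistent, troublesome, f"ROME {mode} rule"))
    return out


def qualify_cdc(record: RespondentRecord,
                definitions: Sequence[SymptomDefinition]) -> list[SymptomRecord]:
    """CDC rule: occurring a_few_times_a_week or everyday, for longer than
    6 months (strict)."""
    out = []
    bank = record.cdc_bank or {}
    for d in definitions:
        entry = bank.get(d.symptom_id)
        if not entry:
            continue
        duration = entry.get("duration")
        freq = entry.get("frequency")
        persistent = duration is not None and DURATION.above(duration, "six_months")
        troublesome = (freq is not None
                       and FREQUENCY_CDC.at_least(freq, "a_few_times_a_week"))
        out.append(SymptomRecord(record.respondent_id, d.symptom_id, d.organ_system,
                                 persistent, troublesome, "CDC frequency rule"))
    return out


def qualify_cis_fatigue(record: RespondentRecord,
                        definition: Optional[SymptomDefinition] = None,
                        cutoff: int = CIS_FATIGUE_CUTOFF) -> list[SymptomRecord]:
    """CIS rule: fatigue-severity score at or above the recommended
    cut-off (35), with the 6-month persistence flag set."""
    bank = record.cis_bank or {}
    score = bank.get("score")
    if score is None:
        return []
    if not (CIS_SCORE_MIN <= score <= CIS_SCORE_MAX):
        raise DataError(f"respondent {record.respondent_id}: CIS score {score} "
                        f"outside [{CIS_SCORE_MIN}, {CIS_SCORE_MAX}]")
    troublesome = score >= cutoff
    persistent = bool(bank.get("persistent_6m"))
    symptom_id = definition.symptom_id if definition else "fatigue"
    system = definition.organ_system if definition else "fatigue_related"
    return [SymptomRecord(record.respondent_id, symptom_id, system,
                          persistent, troublesome, f"CIS cutoff>={cutoff} rule")]


def qualify_scl(record: RespondentRecord,
                definitions: Sequence[SymptomDefinition],
                gap_window: Optional[tuple] = None) -> list[SymptomRecord]:
    """SCL rule: severity moderately or worse at BOTH waves.

    Troublesome reflects the current (first) wave; persistent requires the
    moderate+ report at both timepoints, so qualifies iff both waves are
    at least moderate. Without a second wave the symptom cannot qualify.
    ``gap_window=(lo, hi)`` optionally restricts the inter-wave gap in
    months (off by default; the ~16-month gap is a cohort description,
    not a rule).
    """
    t1, t2 = record.scl_bank_t1, record.scl_bank_t2
    if t1 is None:
        return []
    if t2 is None:
        log.info("respondent %s: second SCL wave absent; SCL symptoms cannot "
                 "qualify", record.respondent_id)
    gap_ok = True
    if gap_window is not None and t2 is not None:
        gap = record.scl_gap_months
        gap_ok = gap is not None and gap_window[0] <= gap <= gap_window[1]
    out = []
    for d in definitions:
        s1 = t1.get(d.symptom_id)
        if s1 is None:
            continue
        troublesome = SEVERITY_SCL.at_least(s1, "moderately")
        s2 = (t2 or {}).get(d.symptom_id)
        persistent = (troublesome and s2 is not None
                      and SEVERITY_SCL.at_least(s2, "moderately") and gap_ok)
        out.append(SymptomRecord(record.respondent_id, d.symptom_id, d.organ_system,
                                 persistent, troublesome, "SCL two-wave rule"))
    return out


# ---------------------------------------------------------------------------
# Union

def evaluate_all(record: RespondentRecord, catalog: SymptomCatalog,
                 per_location_wpi: bool = False,
                 scl_gap_window: Optional[tuple] = None) -> list[SymptomRecord]:
    """All candidate SymptomRecords (qualifying or not) for one respondent."""
    out: list[SymptomRecord] = []
    wpi_defs = catalog.by_instrument("WPI")
    if wpi_defs:
        out += qualify_wpi(record, wpi_defs[0], per_location=per_location_wpi)
    out += qualify_rome(record, catalog.by_instrument("ROME"))
    out += qualify_cdc(record, catalog.by_instrument("CDC"))
    cis_defs = catalog.by_instrument("CIS")
    if cis_defs:
        out += qualify_cis_fatigue(record, cis_defs[0])
    out += qualify_scl(record, catalog.by_instrument("SCL"), gap_window=scl_gap_window)
    return out


def extract_all(record: RespondentRecord, catalog: SymptomCatalog,
                per_location_wpi: bool = False,
                scl_gap_window: Optional[tuple] = None) -> list[SymptomRecord]:
    """Qualifying symptoms for one respondent: the union of the five
    instrument rules, deduplicated by symptom_id and sorted for
    deterministic output."""
    records = evaluate_all(record, catalog, per_location_wpi=per_location_wpi,
                           scl_gap_window=scl_gap_window)
    seen = {}
    for rec in records:
        if rec.qualifies and rec.symptom_id not in seen:
            seen[rec.symptom_id] = rec
    return [seen[sid] for sid in sorted(seen)]


def symptoms_to_frame(symptoms: Sequence[SymptomRecord]) -> pd.DataFrame:
    """Long-format table of SymptomRecords (one row per respondent-symptom)."""
    return pd.DataFrame(
        [{"respondent_id": s.respondent_id, "symptom_id": s.symptom_id,
          "system": s.organ_system, "persistent": s.persistent,
          "troublesome": s.troublesome, "qualifies": s.qualifies}
         for s in symptoms],
        columns=["respondent_id", "symptom_id", "system",
                 "persistent", "troublesome", "qualifies"],
    )
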