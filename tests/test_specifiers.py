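import numpy as np
import pytest

from fsdkit.classify import classify
from fsdkit.cohort import DiseaseCatalog
from fsdkit.errors import DataError
from fsdkit.scales import DURATION, FREQUENCY_CDC
from fsdkit.specifiers import (build_profile, same_system_disease,
                               syndrome_count_table, syndrome_criteria)
from fsdkit.symptoms import SymptomRecord

from conftest import make_record


def qsym(sid, system, rid="R1"):
    return SymptomRecord(rid, sid, system, True, True, "test")


class TestSameSystemDisease:
    def test_matching_system_sets_flag(self):
        rec = make_record(chronic_diseases={"crohns_disease"})
        cls = classify([qsym("abdominal_pain", "gastrointestinal")])
        flags = same_system_disease(rec, cls, DiseaseCatalog.default())
        assert flags["gastrointestinal"]
        assert not any(v for k, v in flags.items() if k != "gastrointestinal")

    def test_system_mismatch_all_false(self):
        rec = make_record(chronic_diseases={"asthma"})
        cls = classify([qsym("abdominal_pain", "gastrointestinal")])
        assert not any(same_system_disease(rec, cls,
                                           DiseaseCatalog.default()).values())

    def test_unassigned_disease_ignored(self):
        rec = make_record(chronic_diseases={"cancer"})
        cls = classify([qsym("abdominal_pain", "gastrointestinal")])
        assert not any(same_system_disease(rec, cls,
                                           DiseaseCatalog.default()).values())

    def test_unknown_code_warns_or_raises_in_strict_mode(self):
        rec = make_record(chronic_diseases={"mystery"})
        cls = classify([qsym("abdominal_pain", "gastrointestinal")])
        flags = same_system_disease(rec, cls, DiseaseCatalog.default())
        assert not any(flags.values())
        with pytest.raises(DataError):
            same_system_disease(rec, cls, DiseaseCatalog.default(), strict=True)

    def test_random_cohort_matches_set_intersection_oracle(self, classified_cohort):
        records, _, symptoms_by_id, classifications = classified_cohort
        catalog = DiseaseCatalog.default()
        by_id = {c.respondent_id: c for c in classifications}
        for rec in records[:300]:
            cls = by_id[rec.respondent_id]
            flags = same_system_disease(rec, cls, catalog)
            disease_systems = {catalog.system_of(c) for c in rec.chronic_diseases}
            disease_systems.discard("unassigned")
            expected = cls.systems_involved & disease_systems
            assert {s for s, v in flags.items() if v} == expected


def oracle_syndromes(rec):
    """Straight-line recoding of the default criteria (banks present)."""
    cis, wpi, cdc, rome = rec.cis_bank, rec.wpi_bank, rec.cdc_bank, rec.rome_bank

    def cdc_freq_ge(item, level):
        entry = cdc.get(item) or {}
        f = entry.get("frequency")
        return f is not None and \
            FREQUENCY_CDC.levels.index(f) >= FREQUENCY_CDC.levels.index(level)

    cfs = (cis.get("score") is not None and cis["score"] >= 35
           and bool(cis.get("persistent_6m"))
           and sum(cdc_freq_ge(i, "monthly")
                   for i in ("sore_throat", "tender_lymph_nodes",
                             "memory_problems", "post_exertional_malaise")) >= 3)

    n_loc = sum(bool(v) for v in (wpi.get("locations") or {}).values())
    dur = wpi.get("duration")
    fm = (n_loc >= 7 and dur is not None
          and DURATION.levels.index(dur) >= 2
          and sum([cis.get("score") is not None and cis["score"] >= 35,
                   cdc_freq_ge("unrefreshing_sleep", "a_few_times_a_week"),
                   cdc_freq_ge("memory_problems", "a_few_times_a_week")]) >= 2)

    ap = rome.get("abdominal_pain") or {}
    days = ap.get("days_per_month")
    ibs = (days is not None and days >= 3
           and ap.get("duration") == "over_six_months"
           and sum(bool(rome.get(a)) for a in
                   ("pain_defecation_related", "pain_stool_freq_change",
                    "pain_stool_form_change")) >= 2)
    return cfs, fm, ibs


def fibromyalgia_boundary_record():
    sites = ["neck", "chest", "abdomen", "upper_back", "lower_back",
             "hip_left", "hip_right"]
    return make_record(
        wpi_bank={"locations": {s: True for s in sites},
                  "duration": "three_to_six_months", "hamper": "a_little"},
        cis_bank={"score": 35, "persistent_6m": False},
        cdc_bank={"memory_problems": {"frequency": "a_few_times_a_week",
                                      "duration": "under_three_months"}},
        rome_bank={"abdominal_pain": {"duration": "six_months",
                                      "frequency": "sometimes",
                                      "days_per_month": 0, "hamper": "a_little"}},
        scl_bank_t1={"dizziness": "not_at_all"},
        scl_bank_t2={"dizziness": "not_at_all"},
    )


class TestSyndromeCriteria:
    def test_symptom_free_record_all_false(self):
        rec = make_record(cis_bank={"score": 8, "persistent_6m": False},
                          wpi_bank={"locations": {}, "duration": None,
                                    "hamper": None},
                          cdc_bank={"headache": {"frequency": "never",
                                                 "duration": "not_present"}},
                          rome_bank={"abdominal_pain": {
                              "duration": "not_present", "frequency": "never",
                              "days_per_month": 0, "hamper": "not_at_all"}})
        assert syndrome_criteria(rec) == (False, False, False)

    def test_fibromyalgia_exact_boundary(self):
        cfs, fm, ibs = syndrome_criteria(fibromyalgia_boundary_record())
        assert fm is True and cfs is False and ibs is False

    def test_missing_bank_is_undetermined_not_false(self):
        rec = make_record()  # all banks empty
        cfs, fm, ibs = syndrome_criteria(rec)
        assert cfs is None and fm is None and ibs is None

    def test_random_records_match_straight_line_recoding(self, classified_cohort):
        records, _, _, _ = classified_cohort
        for rec in records[:200]:
            assert syndrome_criteria(rec) == oracle_syndromes(rec)

    def test_planted_syndromes_recovered_exactly(self, classified_cohort):
        records, truth, _, _ = classified_cohort
        truth_idx = truth.set_index("respondent_id")
        for rec in records:
            cfs, fm, ibs = syndrome_criteria(rec)
            row = truth_idx.loc[rec.respondent_id]
            assert cfs == row["cfs"] and fm == row["fibromyalgia"] \
                and ibs == row["ibs"]

    def test_monotone_in_severity_inputs(self):
        rec = fibromyalgia_boundary_record()
        assert syndrome_criteria(rec)[1] is True
        rec.cis_bank["score"] = 56  # raising severity keeps the flag
        assert syndrome_criteria(rec)[1] is True


class TestSyndromeCountTable:
    def test_counts_partition_cases(self, classified_cohort):
        records, _, _, classifications = classified_cohort
        by_id = {c.respondent_id: c for c in classifications}
        profiles = [build_profile(r, by_id[r.respondent_id]) for r in records]
        table = syndrome_count_table(classifications, profiles)
        assert table["count"].sum() == sum(c.is_case for c in classifications)

    def test_explicit_counts(self):
        cls, profiles = [], []
        specs = [("R1", 1), ("R2", 1), ("R3", 3)]
        for rid, k in specs:
            cls.append(classify([qsym("abdominal_pain", "gastrointestinal", rid)],
                                respondent_id=rid))
            rec = make_record(rid)
            p = build_profile(rec, cls[-1])
            p.cfs = k >= 1
            p.fibromyalgia = k >= 2
            p.ibs = k >= 3
            profiles.append(p)
        table = syndrome_count_table(cls, profiles).set_index("n_syndromes")
        assert table.loc[1, "count"] == 2 and table.loc[3, "count"] == 1
        assert table.loc[0, "count"] == 0 and table.loc[2, "count"] == 0

    def test_profile_flags_same_system_only_for_involved_systems(
            self, classified_cohort):
        records, _, _, classifications = classified_cohort
        by_id = {c.respondent_id: c for c in classifications}
        for rec in records[:200]:
            profile = build_profile(rec, by_id[rec.respondent_id])
            for system, flag in profile.same_system_disease.items():
                if flag:
                    assert system in by_id[rec.respondent_id].systems_involved
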