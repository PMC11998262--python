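import itertools

import numpy as np
import pytest

from fsdkit.scales import DURATION, FREQUENCY_CDC, FREQUENCY_ROME, HAMPER, SEVERITY_SCL
from fsdkit.symptoms import (evaluate_all, extract_all, qualify_cdc,
                             qualify_cis_fatigue, qualify_rome, qualify_scl,
                             qualify_wpi)
from fsdkit.errors import DataError

from conftest import make_record

DURATIONS = DURATION.levels
HAMPERS = HAMPER.levels


def wpi_record(duration, hamper, locations=("neck",), rid="R1"):
    return make_record(rid, wpi_bank={
        "locations": {loc: True for loc in locations},
        "duration": duration, "hamper": hamper})


class TestWpiRule:
    def test_aggregate_qualifying(self):
        rec = wpi_record("over_six_months", "a_lot", ("neck", "chest"))
        (sym,) = qualify_wpi(rec)
        assert sym.qualifies and sym.organ_system == "musculoskeletal"

    def test_per_location_emits_one_per_site(self):
        rec = wpi_record("over_six_months", "a_lot", ("neck", "chest"))
        records = qualify_wpi(rec, per_location=True)
        assert len(records) == 2 and all(s.qualifies for s in records)

    def test_short_duration_fails_persistence(self):
        (sym,) = qualify_wpi(wpi_record("three_to_six_months", "very_much"))
        assert sym.troublesome and not sym.persistent and not sym.qualifies

    def test_missing_duration_with_pain_is_not_persistent(self):
        (sym,) = qualify_wpi(wpi_record(None, "a_lot"))
        assert not sym.persistent

    def test_no_locations_no_record(self):
        assert qualify_wpi(make_record()) == []

    def test_exhaustive_grid_against_truth_table(self):
        # inclusive 6-month boundary: "6 months or longer"
        for duration, hamper in itertools.product(DURATIONS, HAMPERS):
            (sym,) = qualify_wpi(wpi_record(duration, hamper))
            expected = (DURATION.levels.index(duration) >= 3
                        and HAMPER.levels.index(hamper) >= 3)
            assert sym.qualifies == expected, (duration, hamper)


def rome_record(sym_id, duration, frequency=None, days=None, hamper=None):
    return make_record(rome_bank={sym_id: {
        "duration": duration, "frequency": frequency,
        "days_per_month": days, "hamper": hamper}})


class TestRomeRule:
    def test_frequency_route_qualifies(self, catalog):
        rec = rome_record("loose_stools", "over_six_months", "often", 4)
        (sym,) = qualify_rome(rec, catalog.by_instrument("ROME"))
        assert sym.qualifies

    def test_hamper_route(self, catalog):
        rec = rome_record("abdominal_pain", "over_six_months", "often", 8, "a_lot")
        (sym,) = qualify_rome(rec, catalog.by_instrument("ROME"))
        assert sym.qualifies

    def test_mild_bloating_excluded(self, catalog):
        rec = rome_record("bloating", "over_six_months", "sometimes", 1, "a_little")
        (sym,) = qualify_rome(rec, catalog.by_instrument("ROME"))
        assert not sym.troublesome and not sym.qualifies

    def test_six_month_boundary_is_strict(self, catalog):
        rec = rome_record("loose_stools", "six_months", "always", 10)
        (sym,) = qualify_rome(rec, catalog.by_instrument("ROME"))
        assert not sym.persistent

    def test_frequency_grid_against_truth_table(self, catalog):
        defs = [d for d in catalog.by_instrument("ROME")
                if d.symptom_id == "loose_stools"]
        for freq, days, duration in itertools.product(
                FREQUENCY_ROME.levels, (0, 2, 3, 10), DURATIONS):
            rec = rome_record("loose_stools", duration, freq, days)
            (sym,) = qualify_rome(rec, defs)
            persistent = DURATION.levels.index(duration) > 3
            troublesome = FREQUENCY_ROME.levels.index(freq) >= 2 and days >= 3
            assert sym.qualifies == (persistent and troublesome), \
                (freq, days, duration)

    def test_hamper_grid_against_truth_table(self, catalog):
        defs = [d for d in catalog.by_instrument("ROME")
                if d.symptom_id == "abdominal_pain"]
        for hamper, duration in itertools.product(HAMPERS, DURATIONS):
            rec = rome_record("abdominal_pain", duration, hamper=hamper)
            (sym,) = qualify_rome(rec, defs)
            expected = (DURATION.levels.index(duration) > 3
                        and HAMPER.levels.index(hamper) >= 3)
            assert sym.qualifies == expected


class TestCdcRule:
    def test_everyday_joint_pain_qualifies(self, catalog):
        rec = make_record(cdc_bank={"joint_pain": {
            "frequency": "everyday", "duration": "over_six_months"}})
        (sym,) = qualify_cdc(rec, catalog.by_instrument("CDC"))
        assert sym.qualifies and sym.organ_system == "musculoskeletal"

    def test_monthly_muscle_pain_excluded(self, catalog):
        rec = make_record(cdc_bank={"muscle_pain": {
            "frequency": "monthly", "duration": "over_six_months"}})
        (sym,) = qualify_cdc(rec, catalog.by_instrument("CDC"))
        assert not sym.qualifies

    def test_grid_against_truth_table(self, catalog):
        defs = [d for d in catalog.by_instrument("CDC")
                if d.symptom_id == "muscle_pain"]
        for freq, duration in itertools.product(FREQUENCY_CDC.levels, DURATIONS):
            rec = make_record(cdc_bank={"muscle_pain": {
                "frequency": freq, "duration": duration}})
            (sym,) = qualify_cdc(rec, defs)
            expected = (FREQUENCY_CDC.levels.index(freq) >= 3
                        and DURATION.levels.index(duration) > 3)
            assert sym.qualifies == expected


class TestCisRule:
    def test_cutoff_is_inclusive(self):
        rec = make_record(cis_bank={"score": 35, "persistent_6m": True})
        (sym,) = qualify_cis_fatigue(rec)
        assert sym.qualifies

    def test_below_cutoff_excluded(self):
        rec = make_record(cis_bank={"score": 34, "persistent_6m": True})
        (sym,) = qualify_cis_fatigue(rec)
        assert not sym.qualifies

    def test_out_of_range_score_raises(self):
        rec = make_record(cis_bank={"score": 60, "persistent_6m": True})
        with pytest.raises(DataError):
            qualify_cis_fatigue(rec)

    def test_random_pairs_match_direct_predicate(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            score = int(rng.integers(8, 57))
            flag = bool(rng.random() < 0.5)
            rec = make_record(cis_bank={"score": score, "persistent_6m": flag})
            (sym,) = qualify_cis_fatigue(rec)
            assert sym.qualifies == (score >= 35 and flag)


class TestSclRule:
    def scl_record(self, s1, s2):
        return make_record(scl_bank_t1={"dizziness": s1},
                           scl_bank_t2=None if s2 is None else {"dizziness": s2})

    def test_both_waves_moderate_qualifies(self, catalog):
        (sym,) = qualify_scl(self.scl_record("quite_a_bit", "moderately"),
                             catalog.by_instrument("SCL"))
        assert sym.qualifies

    def test_single_wave_excluded(self, catalog):
        (sym,) = qualify_scl(self.scl_record("extremely", "a_little"),
                             catalog.by_instrument("SCL"))
        assert sym.troublesome and not sym.persistent

    def test_missing_second_wave_cannot_qualify(self, catalog):
        (sym,) = qualify_scl(self.scl_record("extremely", None),
                             catalog.by_instrument("SCL"))
        assert not sym.qualifies

    def test_all_severity_pairs_nine_of_25_qualify(self, catalog):
        defs = [d for d in catalog.by_instrument("SCL")
                if d.symptom_id == "dizziness"]
        qualifying = 0
        for s1, s2 in itertools.product(SEVERITY_SCL.levels, repeat=2):
            (sym,) = qualify_scl(self.scl_record(s1, s2), defs)
            expected = (SEVERITY_SCL.levels.index(s1) >= 2
                        and SEVERITY_SCL.levels.index(s2) >= 2)
            assert sym.qualifies == expected
            qualifying += sym.qualifies
        assert qualifying == 9

    def test_optional_gap_window_filter(self, catalog):
        rec = self.scl_record("extremely", "extremely")
        rec.scl_gap_months = 45.0
        defs = catalog.by_instrument("SCL")
        assert qualify_scl(rec, defs)[0].qualifies
        assert not qualify_scl(rec, defs, gap_window=(6, 26))[0].qualifies


def five_instrument_record():
    """Engineered to trip exactly one rule per instrument."""
    return make_record(
        wpi_bank={"locations": {"neck": True}, "duration": "six_months",
                  "hamper": "quite_a_bit"},
        rome_bank={"abdominal_pain": {"duration": "over_six_months",
                                      "frequency": "sometimes",
                                      "days_per_month": 1,
                                      "hamper": "a_lot"}},
        cdc_bank={"joint_pain": {"frequency": "everyday",
                                 "duration": "over_six_months"}},
        cis_bank={"score": 40, "persistent_6m": True},
        scl_bank_t1={"dizziness": "moderately"},
        scl_bank_t2={"dizziness": "extremely"},
    )


class TestExtractAll:
    def test_empty_banks_empty_output(self, catalog):
        assert extract_all(make_record(), catalog) == []

    def test_one_rule_per_instrument_gives_five(self, catalog):
        out = extract_all(five_instrument_record(), catalog)
        assert len(out) == 5
        assert {s.symptom_id for s in out} == {
            "musculoskeletal_pain", "abdominal_pain", "joint_pain",
            "fatigue", "dizziness"}

    def test_idempotent_and_sorted(self, catalog):
        rec = five_instrument_record()
        first, second = extract_all(rec, catalog), extract_all(rec, catalog)
        assert first == second
        assert [s.symptom_id for s in first] == sorted(s.symptom_id for s in first)

    def test_qualifies_iff_persistent_and_troublesome(self, catalog, small_cohort):
        records, _ = small_cohort
        for rec in records[:200]:
            for sym in evaluate_all(rec, catalog):
                assert sym.qualifies == (sym.persistent and sym.troublesome)

    def test_instrument_isolation(self, catalog):
        rec = five_instrument_record()
        baseline = {s.symptom_id for s in extract_all(rec, catalog)}
        rec.cdc_bank["joint_pain"]["frequency"] = "never"
        perturbed = {s.symptom_id for s in extract_all(rec, catalog)}
        assert baseline - perturbed == {"joint_pain"}

    def test_monotone_in_severity(self, catalog):
        # raising any ordered response never un-qualifies a symptom
        rec = five_instrument_record()
        base_ids = {s.symptom_id for s in extract_all(rec, catalog)}
        rec.wpi_bank["hamper"] = "very_much"
        rec.rome_bank["abdominal_pain"]["hamper"] = "very_much"
        rec.scl_bank_t1["dizziness"] = "extremely"
        rec.cis_bank["score"] = 56
        raised_ids = {s.symptom_id for s in extract_all(rec, catalog)}
        assert base_ids <= raised_ids
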