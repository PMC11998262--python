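import pytest

from fsdkit.catalog import SymptomCatalog
from fsdkit.cohort import RespondentRecord
from fsdkit.pipeline import classify_records
from fsdkit.synth import GeneratorConfig, generate


@pytest.fixture(scope="session")
def catalog():
    return SymptomCatalog.default()


@pytest.fixture(scope="session")
def small_cohort():
    """A reusable generated cohort with ground truth (n=800)."""
    records, truth = generate(GeneratorConfig(n=800, seed=11))
    return records, truth


@pytest.fixture(scope="session")
def classified_cohort(small_cohort, catalog):
    records, truth = small_cohort
    symptoms_by_id, classifications = classify_records(records, catalog)
    return records, truth, symptoms_by_id, classifications


def make_record(rid="R1", **kwargs) -> RespondentRecord:
    """A complete-demographics record with empty instrument banks."""
    base = dict(age=45, sex="female", ethnicity="white_european",
                education="medium", relationship_duration=20.0,
                household_size=2, work_hours=32.0, providers_visited=2,
                eq5d=85.0, mini_depression=False, mini_anxiety=False,
                ctq=30.0, lte=0, ldi=1, loneliness=1.0, neuroticism=25.0)
    base.update(kwargs)
    return RespondentRecord(respondent_id=rid, **base)
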