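"""Apply the five symptom rules and the FSD subgroup classification.

Reads results/cohort.csv, extracts qualifying (persistent AND
troublesome) symptoms per respondent, classifies caseness and subgroup,
computes specifier profiles, and reports agreement with the generator's
ground truth (exact by construction — any mismatch would indicate a rule
defect).
"""

from pathlib import Path

import pandas as pd

from fsdkit.classify import classifications_to_frame, tabulate_system_counts
from fsdkit.cohort import apply_exclusions, load_cohort
from fsdkit.pipeline import classify_records
from fsdkit.specifiers import build_profile, profiles_to_frame, syndrome_count_table

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    records = load_cohort(SCRATCH / "cohort.csv")
    included, excluded = apply_exclusions(records)
    print(f"loaded {len(records)}; included {len(included)}, "
          f"excluded {len(excluded)} (basic demographics)")

    _, classifications = classify_records(included)
    frame = classifications_to_frame(classifications)
    frame.to_csv(SCRATCH / "classifications.csv", index=False)

    n_cases = int(frame.is_case.sum())
    print(f"FSD cases: {n_cases} ({100 * n_cases / len(frame):.1f}%)")
    print(frame.subgroup.value_counts().to_string())
    print("\nsystems involved among cases:")
    print(tabulate_system_counts(classifications).to_string(index=False))

    truth = pd.read_csv(SCRATCH / "truth.csv")
    merged = truth.merge(frame, on="respondent_id", suffixes=("_truth", ""))
    agreement = (merged.subgroup_truth == merged.subgroup).mean()
    print(f"\nsubgroup agreement with ground truth: {100 * agreement:.1f}%")

    by_id = {c.respondent_id: c for c in classifications}
    profiles = [build_profile(r, by_id[r.respondent_id]) for r in included]
    profiles_to_frame(profiles).to_csv(SCRATCH / "profiles.csv", index=False)
    print("\ncases by number of functional syndromes met:")
    print(syndrome_count_table(classifications, profiles).to_string(index=False))


if __name__ == "__main__":
    main()
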