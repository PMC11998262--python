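"""Generate the synthetic study cohort.

Draws n=10,000 respondents under the default study conditions (target
caseness prevalence 58.6%, subgroup split ~31/18/51% of cases, planted
covariate odds ratios) and writes the cohort plus its ground truth under
results/. The ground truth is what the later scripts check recovery
against.
"""

from pathlib import Path

from fsdkit.cohort import save_cohort
from fsdkit.synth import GeneratorConfig, generate

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"   # bulky regenerable files live here
SEED, N = 20240, 10_000


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    cfg = GeneratorConfig(n=N, seed=SEED)
    records, truth = generate(cfg)
    save_cohort(records, SCRATCH / "cohort.csv")
    truth.to_csv(SCRATCH / "truth.csv", index=False)
    prev = truth.is_case.mean()
    print(f"wrote {len(records)} respondents (seed {SEED})")
    print(f"planted caseness prevalence: {100 * prev:.1f}% "
          f"(target {100 * cfg.target_prevalence:.1f}%)")
    print(truth.subgroup.value_counts().to_string())


if __name__ == "__main__":
    main()
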