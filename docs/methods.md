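# Methods

## The diagnostic model

The package operationalises the EURONET-SOMA "functional somatic
disorder" (FSD) proposal as an executable rule set over questionnaire
data. FSD requires at least one *persistent* and *troublesome* physical
symptom; cases are sub-classified by how their qualifying symptoms
spread over organ systems:

* **single_symptom** — exactly one qualifying symptom;
* **single_system** — two or more qualifying symptoms, all from one
  organ system;
* **multi_system** — qualifying symptoms from two or more organ systems.

Persistence is defined as a duration of at least six months (the
framework itself suggests three; six matches how population instruments
ask the question), and troublesomeness as moderate-to-severe impact on
the instrument's own Likert scale. Because each instrument phrases
duration and impact differently, there are five rules, one per
instrument:

| Instrument | Persistence | Troublesomeness |
|---|---|---|
| WPI (musculoskeletal pain) | duration **>= 6 months** (inclusive) | hamper >= quite_a_bit |
| ROME-III (8 GI symptoms) | duration **> 6 months** (strict) | frequency >= often on >= 3 days/month, *or* hamper >= quite_a_bit — per symptom |
| CDC inventory (muscle/joint pain, unrefreshing sleep, headache) | duration > 6 months | frequency >= a_few_times_a_week |
| CIS fatigue | explicit 6-month flag | severity score >= 35 (inclusive cut-off) |
| SCL-90 somatization (6 symptoms) | moderate+ severity at **both** of two waves (~16 months apart) | moderate+ severity at the current wave |

The mixed boundary conventions (">= 6 months" for the WPI vs "longer
than 6 months" for ROME/CDC) follow the instruments' question wording;
durations are ordered categories with an explicit `six_months` level so
both conventions are separately testable. A symptom qualifies iff
persistent AND troublesome — this equivalence is structural (a derived
property of `SymptomRecord`), not re-computed.

The symptom-to-organ-system catalog is configuration with a documented
default of 21 symptoms over five systems (cardiorespiratory,
gastrointestinal, musculoskeletal, neurological/other, fatigue-related).
Design choices here that were genuinely open:

* **WPI aggregation.** The duration and hamper questions are asked once
  about "musculoskeletal pain complaints", so the default emits one
  aggregate musculoskeletal-pain symptom; per-location emission is an
  option.
* **ROME disjunct.** Which ROME symptoms use the frequency route versus
  the hamper route is not printed anywhere public; the default applies
  frequency to stool-pattern symptoms (loose stools, hard stools,
  constipation) and hamper to pain/bloating/dyspepsia symptoms.
* **Fatigue system.** Fatigue and unrefreshing sleep sit in a fifth
  `fatigue_related` system that counts toward the subgroup rules; the
  catalog can collapse it into neurological/other.
* **SCL wave gap.** The ~16 (±10) month inter-wave gap is treated as a
  cohort description, not a rule; an optional `[min, max]` gap filter
  exists but is off by default.
* Symptoms are counted by distinct `symptom_id`; a symptom qualifying
  through two instruments counts once.

Exclusion: respondents lacking basic demographics (default: age or sex;
configurable) are removed before analysis. Missingness is handled
complete-case *per analysis*: every comparison and the regression filter
on the variables they use and report their effective n.

## Specifiers

Three optional specifiers are computed per case: same-system chronic
disease (a disease catalog maps self-reported condition codes to the
four disease-bearing organ systems; "unassigned" codes such as cancer
are ignored), concurrent depression/anxiety (self-administered MINI
flags), and the three functional syndromes. Syndrome criteria are
declarative predicate sets over instrument fields evaluated in
three-valued logic — True / False / undetermined (a required instrument
bank is missing) — so complete-case filters can distinguish "no" from
"unknown". The shipped defaults approximate CDC-1994 chronic fatigue
syndrome (CIS >= 35 + 6-month flag + >= 3 of 4 accompanying CDC items at
>= monthly), ACR-2010/FSQ fibromyalgia (WPI >= 7 locations for >= 3
months + 2 of 3 severity markers), and ROME-III IBS (abdominal pain >= 3
days/month with onset > 6 months + >= 2 of 3 defecation/stool-change
features). The CFS accompanying count deliberately uses only the four
CDC items that are *not* themselves candidate FSD symptoms, keeping the
syndrome axis separable from symptom qualification. All thresholds are
config-replaceable; correctness claims are against the configured
criteria, not against any restricted dataset.

## Subgroup statistics

Continuous variables: tie-corrected Kruskal–Wallis
H<sub>corr</sub> = H / (1 − Σ(t³−t)/(n³−n)) with p from χ²(k−1), effect
size ε² = H/(n−1), and Dunn's pairwise z tests

z<sub>ij</sub> = (R̄<sub>i</sub> − R̄<sub>j</sub>) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n<sub>i</sub> + 1/n<sub>j</sub>))

with a Bonferroni family correction: four groups give 6 pairs and a
per-pair threshold 0.05/6 ≈ 0.0083. Categorical variables: Pearson χ²
(no continuity correction) with Cramér's V = sqrt(χ²/(n·min(r−1,c−1))),
where n is the **per-analysis complete-case total** — the published
pairing of V = 0.218 with the anxiety table reproduces only under this
convention, which the tests verify. Effect-size labels use the
conventional bins with a strict ">" boundary (ε²: negligible <= 0.01 <
weak <= 0.04 < moderate <= 0.16 < relatively strong; V: small > 0.1,
medium > 0.3, large > 0.5); the bins are arguments, not constants.
p-values are asymptotic throughout — at the population-cohort sizes this
package targets, exact tests are irrelevant. Display tables mask counts
below 10 as "<10" while keeping the originals for analysis.

## Penalized caseness regression

Binary logistic regression with the elastic-net penalty

min<sub>b0,β</sub> (1/n) Σ log(1+e<sup>−z(b0+x'β)</sup>) + λ[(1−α)/2‖β‖₂² + α‖β‖₁]

(intercept unpenalized). The predictor set comprises per-system
chronic-condition indicators, concurrent anxiety/depression, providers
visited, long-term difficulties, threatening events, loneliness,
neuroticism, childhood trauma, work hours, health status (EQ-5D), sex,
age, ethnicity, education dummies, household size and relationship
duration. The chronic-condition predictors are plain per-system
indicators, **not** the same-system specifier — the specifier is false
for every non-case by construction and would separate the outcome
perfectly.

Procedure: 80/20 train/test split; continuous predictors standardized
with training-set statistics only (the leakage-free choice; the source
description is silent); 10-fold CV over an (α, λ) grid (α default
{0, 0.25, 0.5, 0.75, 1}); λ chosen either at the CV-loss minimum or by
the one-standard-error rule (default `lambda_1se`, matching how such
models are conventionally reported). The CV loss is binomial deviance by
default with Brier score ("mean squared error" read literally) also
implemented — the two readings of the selection loss are both exposed
because the textual description and the reported table header disagree.
Accuracy is the Mann–Whitney/midrank AUC on the held-out test set.

The solver is iteratively reweighted coordinate descent: an outer
quadratic (IRLS) approximation of the mean negative log-likelihood and
an inner cyclic coordinate descent with soft thresholding, warm-started
along the descending λ path. Convergence is declared when no parameter
moves more than `tol` (default 1e−8) in an outer iteration. At λ=0 it
reproduces the Newton MLE to ~1e−14 on small problems; with separable
data the iteration cap (200 outer iterations) bounds divergence. IRLS
weights are floored at 1e−5 and probabilities clipped to [1e−9, 1−1e−9].
The default λ grid descends log-spaced over three decades from the
smallest all-zero-coefficient λ (lasso convention max|x′(y−ȳ)|/n).

## The synthetic cohort generator

The study's raw cohort is access-restricted, so the generator is the
stand-in and is itself first-class, tested code. It emulates: the
demographic and psychosocial covariate marginals of a middle-aged
population survey; caseness drawn from a planted logistic model over the
regression feature set (default planted odds ratios: musculoskeletal
condition 1.8, anxiety 1.6, gastrointestinal condition 1.4, providers
visited 1.25 per provider, male 0.79 — the retained-predictor pattern
of the published model); a conditional subgroup draw
(~31.3/17.7/51.0% of cases) with per-subgroup symptom/system-count
distributions; syndrome planting conditional on subgroup and on the
prerequisite symptom (CFS needs qualifying fatigue, fibromyalgia needs
musculoskeletal pain, IBS needs abdominal pain); and two SCL waves with
a N(16, 10)-month gap. The intercept of the caseness model is calibrated
on the realized covariates (Brent root-finding on the mean predicted
probability) so the cohort hits the target prevalence (default 58.6%) in
expectation; only Bernoulli noise remains.

The central invariant is **round-trip exactness**: item responses are
emitted at-or-above rule thresholds for intended symptoms and strictly
below threshold otherwise, and syndrome-relevant fields are controlled
so the planted syndrome flags are exactly what the criteria engine
recovers. Classification recovery on generated data therefore tests the
rules, not sampling noise. `corrupt()` introduces field-level
missingness at configured rates (deterministic by seed) to exercise the
exclusion and complete-case paths.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: item-level measurement error and response
styles; correlation between psychosocial covariates (they are drawn
independently; only their planted paths into caseness correlate them
with the outcome); symptom severities between the qualifying and
non-qualifying regions of a respondent who almost qualifies; attrition
mechanisms beyond the simple missingness model; and any attempt to match
the restricted cohort's joint covariate distribution. Published
quantities whose raw data are not printed (the 58.6% prevalence itself,
the rank-test H/z values, the published odds ratios and AUC 0.67) are
explicitly out of scope as numeric targets; the published values that
*are* reproduced (contingency χ²/V, the ε² pairings, the 0.0083
threshold) are those computable from printed inputs.

## Problem sizes and numerical choices

Tests use cohorts of n = 800–6,000; planted-coefficient recovery uses
n = 20,000 (MLE standard errors ≈ 0.05–0.08 for the rarer binary
predictors, comfortably inside the ±0.15 recovery band); the λ.1se
selection property uses 20 seeds of n = 2,000 with 3 true and 7 null
standardized predictors. The analysis scripts use n = 10,000. Oracle
agreement for the rank statistics is required to 1e−10 on fifty random
small datasets per statistic, and MLE agreement to 1e−6 on a 50×3
problem. Ties in all rank computations use midranks. Kruskal–Wallis on
groups with zero total variance is defined as H = 0. Contingency tables
with a zero margin are rejected with the degenerate row/column named.

## Known limitations

* The exact symptom catalog, the per-symptom ROME disjunct assignment
  and the precise syndrome operationalisations of the original study are
  unpublished; the defaults are documented approximations and everything
  is config-driven, but no claim is made that the defaults reproduce the
  original assignments.
* Differential diagnosis ("better explained by another medical
  condition") is deliberately not modelled, matching the original
  operationalisation's stated inability to apply it.
* No multiple imputation; complete-case analysis throughout.
* The penalized model's reported coefficients are on the standardized
  training scale; odds ratios are per SD for continuous predictors.
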