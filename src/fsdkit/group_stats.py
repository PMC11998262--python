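"""Subgroup-comparison statistics.

Continuous variables are compared across the four FSD subgroups with a
tie-corrected Kruskal–Wallis test, the epsilon-squared effect size
(eps^2 = H/(n-1)) and Dunn's pairwise z tests under a Bonferroni family
correction (4 groups -> 6 pairs -> threshold 0.05/6 ~= 0.0083).
Categorical variables use the Pearson chi-square test (no continuity
correction) with Cramer's V = sqrt(chi2 / (n * min(r-1, c-1))), where n
is the per-analysis complete-case total, not the cohort size.

Effect-size interpretation uses the conventional bins with a strict ">"
boundary: eps^2 negligible <= 0.01 < weak <= 0.04 < moderate <= 0.16 <
relatively strong; V small > 0.1, medium > 0.3, large > 0.5.

p-values come from asymptotic chi-square / normal distributions — at
population-cohort scale exact tests are irrelevant.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import SUBGROUPS
from .errors import ContractViolation, DataError

BONFERRONI_FAMILY_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Result containers

@dataclass(frozen=True)
class PairwiseComparison:
    group_a: str
    group_b: str
    z: float
    p: float
    p_adjusted: float
    significant: bool


@dataclass
class ComparisonResult:
    variable: str
    kind: str                     # "continuous" | "categorical"
    groups: tuple
    statistic: float              # H or chi-square
    df: int
    p: float
    effect_size: float            # epsilon-squared or Cramer's V
    effect_label: str
    n_effective: int
    posthoc: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Kruskal–Wallis and epsilon squared

def kruskal_wallis(samples: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal–Wallis H over k >= 2 nonempty groups.

    Returns (H, df, p) with p from the chi-square(k-1) upper tail. When
    every value in every group is identical the statistic is defined as
    H = 0 (p = 1).
    """
    if len(samples) < 2:
        raise ContractViolation("kruskal_wallis needs at least two groups")
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ContractViolation("kruskal_wallis groups must be nonempty")
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, df, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), df, float(p)


def epsilon_squared(h: float, n: int) -> float:
    """Kruskal–Wallis effect size eps^2 = H / (n - 1)."""
    if n < 2:
        raise ContractViolation("epsilon_squared needs n >= 2")
    return h / (n - 1)


#: (upper bound, label) with strict ">" boundaries: a value exactly at a
#: bound keeps the lower label.
EPSILON_SQUARED_BINS = ((0.01, "negligible"), (0.04, "weak"),
                        (0.16, "moderate"), (float("inf"), "relatively_strong"))
CRAMERS_V_BINS = ((0.1, "negligible"), (0.3, "small"),
                  (0.5, "medium"), (float("inf"), "large"))


def _label(value: float, bins) -> str:
    for bound, name in bins:
        if value <= bound:
            return name
    return bins[-1][1]  # pragma: no cover


def label_epsilon_squared(value: float, bins=EPSILON_SQUARED_BINS) -> str:
    return _label(value, bins)


def label_cramers_v(value: float, bins=CRAMERS_V_BINS) -> str:
    return _label(value, bins)


# ---------------------------------------------------------------------------
# Dunn's post hoc

def dunn_posthoc(samples: Sequence[Sequence[float]],
                 group_labels: Optional[Sequence[str]] = None,
                 alpha_family: float = BONFERRONI_FAMILY_ALPHA,
                 ) -> list[PairwiseComparison]:
    """Dunn's (1964) pairwise z tests on the pooled midranks, with a
    Bonferroni correction over the k(k-1)/2 comparisons.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)),
    where T = sum(t^3 - t) / (12(N-1)) corrects for ties. A pair is
    significant when its raw p is below alpha_family / m (for 4 groups,
    0.05/6 ~= 0.00833).
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(a.size == 0 for a in arrays):
        raise ContractViolation("dunn_posthoc groups must be nonempty")
    k = len(arrays)
    labels = list(group_labels) if group_labels is not None else \
        [f"group_{i}" for i in range(k)]
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = []
    start = 0
    for a in arrays:
        mean_ranks.append(ranks[start:start + a.size].mean())
        start += a.size

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (12.0 * (n_total - 1))
                if n_total > 1 else 0.0)
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    m = k * (k - 1) // 2
    threshold = alpha_family / m
    out = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(variance_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        out.append(PairwiseComparison(labels[i], labels[j], float(z), float(p),
                                      float(min(1.0, p * m)), bool(p < threshold)))
    return out


# ---------------------------------------------------------------------------
# Chi-square and Cramer's V

def chi_square(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table (no continuity
    correction). Raises DataError naming any all-zero row or column."""
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2:
        raise ContractViolation("chi_square expects a 2-D table")
    if (counts < 0).any():
        raise DataError("chi_square table has negative counts")
    zero_rows = np.where(counts.sum(axis=1) == 0)[0]
    zero_cols = np.where(counts.sum(axis=0) == 0)[0]
    if zero_rows.size or zero_cols.size:
        parts = []
        if zero_rows.size:
            parts.append(f"row(s) {zero_rows.tolist()}")
        if zero_cols.size:
            parts.append(f"column(s) {zero_cols.tolist()}")
        raise DataError("zero margin in " + " and ".join(parts))
    result = stats.chi2_contingency(counts, correction=False)
    return float(result.statistic), int(result.dof), float(result.pvalue)


def cramers_v(chi2: float, n: int, r: int, c: int) -> float:
    """Cramer's V = sqrt(chi2 / (n * min(r-1, c-1))).

    n is the complete-case total of the table the chi-square was computed
    on (per-analysis n), not the overall cohort size.
    """
    if n <= 0:
        raise ContractViolation("cramers_v needs n > 0")
    return float(np.sqrt(chi2 / (n * min(r - 1, c - 1))))


# ---------------------------------------------------------------------------
# Small-cell masking

@dataclass
class MaskedTable:
    """Display table with counts below threshold rendered '<t>'; the
    original counts are kept so analyses are untouched."""

    display: pd.DataFrame
    original: pd.DataFrame
    threshold: int

    def unmask(self) -> pd.DataFrame:
        return self.original.copy()


def mask_small_cells(table: pd.DataFrame, threshold: int = 10) -> MaskedTable:
    original = table.copy()
    display = table.astype(object).copy()
    numeric = table.to_numpy()
    mask = numeric < threshold
    for i in range(display.shape[0]):
        for j in range(display.shape[1]):
            display.iat[i, j] = f"<{threshold}" if mask[i, j] else str(int(numeric[i, j]))
    return MaskedTable(display=display, original=original, threshold=threshold)


# ---------------------------------------------------------------------------
# Table builders

DEFAULT_CONTINUOUS = ("age", "eq5d", "household_size", "ldi", "lte",
                      "neuroticism", "relationship_duration", "work_hours",
                      "loneliness", "ctq", "providers_visited")
DEFAULT_CATEGORICAL = ("sex", "ethnicity", "education",
                       "mini_anxiety", "mini_depression")


def compare_continuous(frame: pd.DataFrame, variable: str,
                       group_col: str = "subgroup",
                       groups: Sequence[str] = SUBGROUPS) -> ComparisonResult:
    """Kruskal–Wallis + eps^2 + Dunn grid for one continuous variable,
    complete-case on that variable."""
    sub = frame[[variable, group_col]].dropna()
    samples = [sub.loc[sub[group_col] == g, variable].to_numpy(dtype=float)
               for g in groups]
    h, df, p = kruskal_wallis(samples)
    n = int(sub.shape[0])
    eps2 = epsilon_squared(h, n)
    posthoc = dunn_posthoc(samples, group_labels=list(groups))
    return ComparisonResult(variable, "continuous", tuple(groups), h, df, p,
                            eps2, label_epsilon_squared(eps2), n, posthoc)


def compare_categorical(frame: pd.DataFrame, variable: str,
                        group_col: str = "subgroup",
                        groups: Sequence[str] = SUBGROUPS) -> ComparisonResult:
    """Pearson chi-square + Cramer's V for one categorical variable,
    complete-case on that variable."""
    sub = frame[[variable, group_col]].dropna()
    table = pd.crosstab(sub[variable], sub[group_col])
    table = table.reindex(columns=[g for g in groups if g in table.columns])
    counts = table.to_numpy()
    chi2, df, p = chi_square(counts)
    n = int(counts.sum())
    v = cramers_v(chi2, n, *counts.shape)
    return ComparisonResult(variable, "categorical", tuple(table.columns), chi2,
                            df, p, v, label_cramers_v(v), n)


def build_comparison_tables(frame: pd.DataFrame,
                            continuous: Sequence[str] = DEFAULT_CONTINUOUS,
                            categorical: Sequence[str] = DEFAULT_CATEGORICAL,
                            group_col: str = "subgroup") -> dict:
    """Subgroup-comparison tables over a cohort frame that already carries
    a subgroup column (and any specifier columns to be compared).

    Returns {"continuous": frame, "categorical": frame,
    "results": {variable: ComparisonResult}}. Each row reports its own
    complete-case n.
    """
    results: dict[str, ComparisonResult] = {}
    cont_rows, cat_rows = [], []
    for var in continuous:
        if var not in frame.columns:
            continue
        res = compare_continuous(frame, var, group_col=group_col)
        results[var] = res
        sig_pairs = "; ".join(f"{c.group_a} vs {c.group_b}"
                              for c in res.posthoc if c.significant)
        cont_rows.append({"variable": var, "n": res.n_effective,
                          "H": res.statistic, "df": res.df, "p": res.p,
                          "epsilon_squared": res.effect_size,
                          "label": res.effect_label,
                          "significant_pairs": sig_pairs})
    for var in categorical:
        if var not in frame.columns:
            continue
        res = compare_categorical(frame, var, group_col=group_col)
        results[var] = res
        cat_rows.append({"variable": var, "n": res.n_effective,
                         "chi2": res.statistic, "df": res.df, "p": res.p,
                         "cramers_v": res.effect_size, "label": res.effect_label})
    return {"continuous": pd.DataFrame(cont_rows),
            "categorical": pd.DataFrame(cat_rows),
            "results": results}
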