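"""Published reference values from the originating population-cohort
analysis, used as fixed verification inputs.

Only quantities whose full inputs are printed are reproduced here: the
2x4 subgroup contingency tables (cell counts) together with their
reported chi-square and Cramer's V, the reported Kruskal–Wallis H /
epsilon-squared pairings used as formula-consistency checks, and the
reported Bonferroni significance threshold. Rank-based statistics on the
raw cohort cannot be recomputed from the publication and are not listed.
"""

#: Subgroup column order of the published tables.
SUBGROUP_ORDER = ("non_case", "single_symptom", "single_system", "multi_system")

#: Sex x subgroup counts (rows: female, male), with reported chi2 and V.
SEX_TABLE = {
    "counts": [[18662, 9516, 5987, 18374],
               [18184, 6805, 3226, 8173]],
    "rows": ("female", "male"),
    "chi2": 2347.9,
    "cramers_v": 0.162,
}

#: Concurrent anxiety diagnosis x subgroup counts (rows: no, yes). Note
#: the table's own complete-case total (65,697) is smaller than the
#: cohort (88,927); the reported V matches only with the per-analysis n.
ANXIETY_TABLE = {
    "counts": [[26376, 11553, 6137, 16346],
               [709, 626, 747, 3203]],
    "rows": ("no_anxiety", "anxiety"),
    "chi2": 3128.6,
    "cramers_v": 0.218,
}

#: Full-cohort size behind the continuous comparisons (sum of the four
#: subgroup counts: 36,846 + 16,321 + 9,213 + 26,547).
COHORT_N = 88927

#: Reported (H, epsilon-squared) pairings consistent with
#: eps2 = H / (n - 1) at the cohort n.
EPSILON_SQUARED_CHECKS = (
    {"variable": "providers_visited", "H": 7486.8, "epsilon_squared": 0.0842},
    {"variable": "eq5d", "H": 10534.0, "epsilon_squared": 0.118},
)

#: Reported pairwise significance threshold: 0.05 over the six pairwise
#: comparisons among four groups.
REPORTED_PAIRWISE_THRESHOLD = 0.0083
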