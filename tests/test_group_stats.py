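import numpy as np
import pandas as pd
import pytest

from fsdkit.errors import ContractViolation, DataError
from fsdkit.group_stats import (build_comparison_tables, chi_square,
                                compare_categorical, compare_continuous,
                                cramers_v, dunn_posthoc, epsilon_squared,
                                kruskal_wallis, label_cramers_v,
                                label_epsilon_squared, mask_small_cells)
from fsdkit.pipeline import analysis_frame


# ---------------------------------------------------------------------------
# Independent brute-force oracles (no scipy)

def midranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_kruskal(groups):
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    ranks = midranks(pooled)
    h = 0.0
    start = 0
    for g in groups:
        rsum = sum(ranks[start:start + len(g)])
        h += rsum ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    ties = {}
    for x in pooled:
        ties[x] = ties.get(x, 0) + 1
    correction = 1.0 - sum(t ** 3 - t for t in ties.values()) / (n ** 3 - n)
    return h / correction if correction > 0 else 0.0


def oracle_mean_ranks(groups):
    pooled = [x for g in groups for x in g]
    ranks = midranks(pooled)
    out, start = [], 0
    for g in groups:
        out.append(sum(ranks[start:start + len(g)]) / len(g))
        start += len(g)
    return out


def oracle_chi2(table):
    table = [list(map(float, row)) for row in table]
    rowsums = [sum(r) for r in table]
    colsums = [sum(r[j] for r in table) for j in range(len(table[0]))]
    total = sum(rowsums)
    stat = 0.0
    for i, row in enumerate(table):
        for j, obs in enumerate(row):
            exp = rowsums[i] * colsums[j] / total
            stat += (obs - exp) ** 2 / exp
    return stat


def random_groups(rng, k=4, tie_prone=True):
    sizes = rng.integers(3, 12, size=k)
    if tie_prone:
        return [rng.integers(0, 6, size=s).astype(float).tolist() for s in sizes]
    return [rng.normal(size=s).tolist() for s in sizes]


# ---------------------------------------------------------------------------

class TestKruskalWallis:
    def test_hand_computed_example(self):
        # ranks 1,2 vs 3,4 -> R1=3, R2=7 -> H = 2.4
        h, df, p = kruskal_wallis([[1, 2], [3, 4]])
        assert h == pytest.approx(2.4, abs=1e-12)
        assert df == 1

    def test_symmetric_groups_give_zero(self):
        h, _, _ = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_defined_as_zero(self):
        h, df, p = kruskal_wallis([[5, 5], [5, 5, 5]])
        assert h == 0.0 and p == 1.0

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for i in range(50):
            groups = random_groups(rng, k=int(rng.integers(2, 5)),
                                   tie_prone=bool(i % 2))
            h, _, _ = kruskal_wallis(groups)
            assert abs(h - oracle_kruskal(groups)) < 1e-10

    def test_two_groups_equal_dunn_z_squared(self):
        # tie-corrected H for k=2 equals the squared normal statistic
        rng = np.random.default_rng(8)
        for _ in range(10):
            groups = random_groups(rng, k=2)
            h, _, _ = kruskal_wallis(groups)
            (pair,) = dunn_posthoc(groups)
            assert h == pytest.approx(pair.z ** 2, rel=1e-9, abs=1e-9)

    def test_preconditions(self):
        with pytest.raises(ContractViolation):
            kruskal_wallis([[1, 2]])
        with pytest.raises(ContractViolation):
            kruskal_wallis([[1, 2], []])


class TestEpsilonSquared:
    def test_formula_and_labels(self):
        assert epsilon_squared(0.0, 10) == 0.0
        assert epsilon_squared(2.4, 4) == pytest.approx(0.8)
        assert label_epsilon_squared(0.118) == "moderate"
        # strict ">" boundary convention: a value at the bound keeps the
        # lower label
        assert label_epsilon_squared(0.01) == "negligible"
        assert label_epsilon_squared(0.04) == "weak"
        assert label_epsilon_squared(0.16) == "moderate"
        assert label_epsilon_squared(0.2) == "relatively_strong"

    def test_bounded_for_real_data(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            groups = random_groups(rng)
            h, _, _ = kruskal_wallis(groups)
            eps2 = epsilon_squared(h, sum(len(g) for g in groups))
            assert 0.0 <= eps2 <= 1.0


class TestDunnPosthoc:
    def test_four_groups_six_pairs(self):
        rng = np.random.default_rng(1)
        pairs = dunn_posthoc(random_groups(rng, k=4))
        assert len(pairs) == 6

    def test_identical_groups_not_significant(self):
        groups = [[1, 2, 3], [1, 2, 3], [10, 11, 12], [20, 21, 22]]
        pairs = dunn_posthoc(groups, group_labels=list("abcd"))
        first = next(p for p in pairs if {p.group_a, p.group_b} == {"a", "b"})
        assert first.z == pytest.approx(0.0, abs=1e-12)
        assert not first.significant

    def test_sign_matches_mean_rank_difference_and_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            groups = random_groups(rng, k=4)
            mean_ranks = oracle_mean_ranks(groups)
            for pair in dunn_posthoc(groups):
                i = int(pair.group_a.split("_")[1])
                j = int(pair.group_b.split("_")[1])
                diff = mean_ranks[i] - mean_ranks[j]
                assert np.sign(pair.z) == np.sign(diff) or diff == 0

    def test_bonferroni_subset_property(self):
        rng = np.random.default_rng(10)
        groups = [rng.normal(loc=m, size=30).tolist() for m in (0, 0.2, 1, 3)]
        pairs = dunn_posthoc(groups)
        for p in pairs:
            if p.significant:          # alpha/6 significant ...
                assert p.p < 0.05      # ... implies alpha significant
            assert p.p_adjusted >= p.p


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        stat, df, p = chi_square([[10, 20, 30], [20, 40, 60]])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert df == 2

    def test_closed_form_2x2(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 60*(100-400)^2/(30*30*30*30)
        stat, df, _ = chi_square([[10, 20], [20, 10]])
        assert stat == pytest.approx(20.0 / 3.0, rel=1e-12)
        assert df == 1

    def test_zero_margin_named(self):
        with pytest.raises(DataError, match="column.*1"):
            chi_square([[5, 0], [3, 0]])
        with pytest.raises(DataError, match="row.*0"):
            chi_square([[0, 0], [3, 2]])

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        table = rng.integers(1, 50, size=(3, 4))
        base, _, _ = chi_square(table)
        perm, _, _ = chi_square(table[[2, 0, 1]][:, [3, 1, 0, 2]])
        assert base == pytest.approx(perm, rel=1e-12)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            table = rng.integers(1, 40, size=(int(rng.integers(2, 4)),
                                              int(rng.integers(2, 5))))
            stat, _, _ = chi_square(table)
            assert abs(stat - oracle_chi2(table)) < 1e-10


class TestCramersV:
    def test_zero_and_range(self):
        assert cramers_v(0.0, 100, 2, 4) == 0.0
        rng = np.random.default_rng(7)
        for _ in range(20):
            table = rng.integers(1, 50, size=(3, 3))
            stat, _, _ = chi_square(table)
            v = cramers_v(stat, int(table.sum()), 3, 3)
            assert 0.0 <= v <= 1.0

    def test_labels_with_strict_boundary(self):
        assert label_cramers_v(0.1) == "negligible"
        assert label_cramers_v(0.11) == "small"
        assert label_cramers_v(0.3) == "small"
        assert label_cramers_v(0.31) == "medium"
        assert label_cramers_v(0.51) == "large"


class TestMaskSmallCells:
    def test_boundary_and_round_trip(self):
        table = pd.DataFrame([[9, 10], [0, 123]], columns=["a", "b"])
        masked = mask_small_cells(table)
        assert masked.display.iloc[0, 0] == "<10"
        assert masked.display.iloc[0, 1] == "10"
        assert masked.display.iloc[1, 0] == "<10"
        pd.testing.assert_frame_equal(masked.unmask(), table)

    def test_all_zero_table(self):
        table = pd.DataFrame([[0, 0], [0, 0]])
        masked = mask_small_cells(table)
        assert (masked.display == "<10").all().all()


@pytest.fixture(scope="module")
def frame(classified_cohort):
    records, _, _, classifications = classified_cohort
    return analysis_frame(records, classifications)


class TestComparisonTables:
    def test_structure_and_effective_n(self, frame):
        tables = build_comparison_tables(frame)
        cont, cat = tables["continuous"], tables["categorical"]
        assert set(cont.columns) >= {"variable", "n", "H", "p",
                                     "epsilon_squared", "label"}
        assert set(cat.columns) >= {"variable", "n", "chi2", "cramers_v"}
        # complete data in the generator: every row uses the full cohort
        assert (cont["n"] == len(frame)).all()

    def test_continuous_posthoc_grid_size(self, frame):
        res = compare_continuous(frame, "age")
        assert len(res.posthoc) == 6 and res.df == 3

    def test_categorical_uses_per_analysis_n(self, frame):
        frame2 = frame.copy()
        frame2.loc[frame2.index[:100], "sex"] = None
        res = compare_categorical(frame2, "sex")
        assert res.n_effective == len(frame2) - 100

    def test_group_counts_partition(self, frame):
        res = compare_categorical(frame, "sex")
        sub = frame[["sex", "subgroup"]].dropna()
        assert res.n_effective == len(sub)
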