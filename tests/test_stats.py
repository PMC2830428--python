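"""Exact Fisher test, rank-sum test, summaries and the class ladder."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from promdiver.stats import (
    ComparisonResult,
    ContingencyTable2x2,
    class_ladder,
    contingency_2x2,
    fisher_exact,
    fraction,
    median,
    p_display,
    wilcoxon_rank_sum,
)


def fisher_enumeration_oracle(a, b, c, d, alternative="two_sided") -> Fraction:
    """Exact-rational p by enumerating every table with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {
        aa: math.comb(r1, aa) * math.comb(r2, c1 - aa) for aa in range(lo, hi + 1)
    }
    denom = sum(weights.values())
    if alternative == "greater":
        num = sum(w for aa, w in weights.items() if aa >= a)
    elif alternative == "less":
        num = sum(w for aa, w in weights.items() if aa <= a)
    else:
        num = sum(w for w in weights.values() if w <= weights[a])
    return Fraction(num, denom)


def rank_sum_enumeration_oracle(x, y, alternative="two_sided") -> float:
    """Full enumeration over all assignments of pooled ranks to the x sample."""
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    w = ranks[:n1].sum()
    mu = n1 * ranks.sum() / n
    d = abs(w - mu)
    eps = 1e-9
    sums = [sum(ranks[list(idx)]) for idx in itertools.combinations(range(n), n1)]
    if alternative == "greater":
        return sum(s >= w - eps for s in sums) / len(sums)
    if alternative == "less":
        return sum(s <= w + eps for s in sums) / len(sums)
    hits = sum(s <= mu - d + eps or s >= mu + d - eps for s in sums)
    return min(1.0, hits / len(sums))


class TestFisher:
    def test_worked_table(self):
        assert fisher_exact(ContingencyTable2x2(3, 1, 1, 3)) == pytest.approx(34 / 70)

    def test_identical_rows_give_one(self):
        assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_transpose_symmetry(self, rng):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 30, 4))
            if a + b + c + d == 0:
                continue
            t = ContingencyTable2x2(a, b, c, d)
            tt = ContingencyTable2x2(a, c, b, d)
            assert fisher_exact(t) == pytest.approx(fisher_exact(tt), rel=1e-9)

    def test_row_and_column_swap_invariance(self, rng):
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 25, 4))
            if a + b + c + d == 0:
                continue
            p1 = fisher_exact(ContingencyTable2x2(a, b, c, d))
            p2 = fisher_exact(ContingencyTable2x2(d, c, b, a))
            assert p1 == pytest.approx(p2, rel=1e-9)

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_matches_rational_enumeration(self, rng, alternative):
        for _ in range(150):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, 4))
            if a + b + c + d == 0:
                continue
            p = fisher_exact(ContingencyTable2x2(a, b, c, d), alternative)
            oracle = float(fisher_enumeration_oracle(a, b, c, d, alternative))
            assert p == pytest.approx(oracle, rel=1e-7)

    def test_matches_scipy_on_large_margins(self, rng):
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(0, 2000, 4))
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            ours = fisher_exact(ContingencyTable2x2(a, b, c, d))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(ContingencyTable2x2(0, 0, 0, 0))

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 0, 0, 1)


class TestWilcoxon:
    def test_worked_exact_examples(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4])[1] == pytest.approx(2 / 6)
        assert wilcoxon_rank_sum([1], [2])[1] == 1.0

    def test_identical_multisets_give_one(self):
        for mode in ("exact", "normal"):
            assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], mode=mode)[1] == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_exact_matches_permutation_enumeration(self, rng, alternative):
        for _ in range(40):
            n1, n2 = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            pool = rng.choice(1000, size=n1 + n2, replace=False).astype(float)
            x, y = pool[:n1], pool[n1:]
            _, p = wilcoxon_rank_sum(x, y, alternative=alternative, mode="exact")
            assert p == pytest.approx(
                rank_sum_enumeration_oracle(x, y, alternative), abs=1e-12
            )

    def test_exact_matches_scipy_exact(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            pool = rng.choice(10_000, size=n1 + n2, replace=False).astype(float)
            _, p = wilcoxon_rank_sum(pool[:n1], pool[n1:], mode="exact")
            ref = scipy.stats.mannwhitneyu(pool[:n1], pool[n1:], method="exact").pvalue
            assert p == pytest.approx(ref, rel=1e-12)

    def test_normal_close_to_exact_balanced_midsize(self, rng):
        # the corrected normal approximation is within 0.01 of the exact
        # distribution once both groups have >= 10 observations
        for _ in range(15):
            n = int(rng.integers(21, 31))
            n1 = int(rng.integers(10, n - 9))
            pool = rng.choice(100_000, size=n, replace=False).astype(float)
            x, y = pool[:n1], pool[n1:]
            _, p_exact = wilcoxon_rank_sum(x, y, mode="exact")
            _, p_norm = wilcoxon_rank_sum(x, y, mode="normal")
            assert abs(p_exact - p_norm) <= 0.01

    def test_normal_matches_scipy_with_ties(self, rng):
        for _ in range(20):
            x = rng.integers(0, 8, size=40).astype(float)
            y = rng.integers(1, 9, size=35).astype(float)
            _, p = wilcoxon_rank_sum(x, y, mode="normal")
            ref = scipy.stats.mannwhitneyu(
                x, y, method="asymptotic", use_continuity=True
            ).pvalue
            assert p == pytest.approx(ref, rel=1e-9)

    @given(
        st.lists(st.integers(0, 10_000), min_size=2, max_size=20, unique=True),
        st.integers(1, 5),
    )
    @settings(deadline=None, derandomize=True)
    def test_monotone_transform_invariance(self, pool, cut):
        cut = min(cut, len(pool) - 1)
        x = [float(v) for v in pool[:cut]]
        y = [float(v) for v in pool[cut:]]
        _, p1 = wilcoxon_rank_sum(x, y)
        transform = lambda v: math.exp(v / 1000.0) + v**3
        _, p2 = wilcoxon_rank_sum([transform(v) for v in x], [transform(v) for v in y])
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_p_in_unit_interval(self, rng):
        for _ in range(30):
            x = rng.normal(size=int(rng.integers(1, 40)))
            y = rng.normal(size=int(rng.integers(1, 40)))
            _, p = wilcoxon_rank_sum(x, y)
            assert 0 < p <= 1


class TestSummaries:
    @pytest.mark.parametrize(
        "values,expected", [([1, 2, 3], 2.0), ([1, 2, 3, 4], 2.5), ([7, 7, 7], 7.0)]
    )
    def test_median(self, values, expected):
        assert median(values) == expected

    def test_median_empty_rejected(self):
        with pytest.raises(ValueError):
            median([])

    @pytest.mark.parametrize(
        "num,den,decimals,expected",
        [
            (14410, 19636, 0, 73.0),
            (10665, 14719, 1, 72.5),
            (14783, 15180, 1, 97.4),
            (0, 10, 1, 0.0),
        ],
    )
    def test_fraction(self, num, den, decimals, expected):
        assert fraction(num, den, decimals) == expected

    def test_fraction_half_up(self):
        assert fraction(1, 8, 0) == 13.0  # 12.5% rounds up, not to even

    def test_fraction_zero_denominator(self):
        with pytest.raises(ValueError):
            fraction(1, 0)


class TestContingency:
    def test_balanced(self):
        t = contingency_2x2({"A": True, "B": False, "C": True, "D": False}, {"A", "B"}, {"C", "D"})
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_extreme_table(self):
        flags = {f"x{i}": True for i in range(4)} | {f"y{i}": False for i in range(6)}
        t = contingency_2x2(flags, {f"x{i}" for i in range(4)}, {f"y{i}" for i in range(6)})
        assert (t.a, t.b, t.c, t.d) == (4, 0, 0, 6)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            contingency_2x2({"A": True, "B": True}, {"A", "B"}, {"B"})

    def test_unknown_flags_dropped_and_counted(self):
        flags = {"A": True, "B": None}
        t = contingency_2x2(flags, {"A", "B"}, {"C"})
        assert t.n_unknown_dropped == 2  # B is None, C absent
        assert (t.a, t.b) == (1, 0)

    def test_matches_recount_oracle(self, rng):
        genes = [f"g{i}" for i in range(200)]
        flags = {g: bool(rng.random() < 0.3) for g in genes}
        g1, g2 = set(genes[:90]), set(genes[90:])
        t = contingency_2x2(flags, g1, g2)
        assert t.a == sum(flags[g] for g in g1)
        assert t.b == sum(not flags[g] for g in g1)
        assert t.c == sum(flags[g] for g in g2)
        assert t.d == sum(not flags[g] for g in g2)


def make_profiles(class_sizes):
    rows = []
    for cls, size in zip(["SP", "AP2", "AP3_4", "AP5plus"], class_sizes):
        for i in range(size):
            rows.append({"gene_id": f"{cls}_{i}", "promoter_class": cls})
    return pd.DataFrame(rows)


class TestLadder:
    LABELS = ["AP_vs_SP", "AP2_vs_SP", "AP3_4_vs_AP2", "AP5plus_vs_AP3_4"]

    def test_fixed_order_and_labels(self, rng):
        profiles = make_profiles([30, 30, 30, 30])
        data = {g: float(v) for g, v in zip(profiles["gene_id"], rng.normal(size=120))}
        shuffled = profiles.sample(frac=1, random_state=5)
        for prof in (profiles, shuffled):
            result = class_ladder(data, prof, "rank_sum")
            assert [c.label for c in result.comparisons] == self.LABELS
            assert list(result.class_summaries["class"]) == ["SP", "AP2", "AP3_4", "AP5plus"]

    def test_planted_monotone_flag_fractions_all_rungs_significant(self):
        rng = np.random.default_rng(77)
        profiles = make_profiles([2000, 2000, 2000, 2000])
        probs = dict(zip(["SP", "AP2", "AP3_4", "AP5plus"], [0.05, 0.10, 0.20, 0.40]))
        data = {
            g: bool(rng.random() < probs[c])
            for g, c in zip(profiles["gene_id"], profiles["promoter_class"])
        }
        result = class_ladder(data, profiles, "fisher")
        assert all(c.p_value < 0.01 for c in result.comparisons)

    def test_rank_sum_summaries_are_medians(self, rng):
        profiles = make_profiles([11, 11, 11, 11])
        data = {g: float(v) for g, v in zip(profiles["gene_id"], rng.normal(size=44))}
        result = class_ladder(data, profiles, "rank_sum")
        sp_median = median(
            [data[g] for g in profiles[profiles["promoter_class"] == "SP"]["gene_id"]]
        )
        summaries = result.class_summaries.set_index("class")["summary"]
        assert summaries["SP"] == pytest.approx(sp_median)
        assert result.comparisons[0].group_summaries[1] == pytest.approx(sp_median)

    def test_empty_class_rung_skipped_with_warning(self, rng):
        profiles = make_profiles([10, 10, 0, 10])
        data = {g: float(v) for g, v in zip(profiles["gene_id"], rng.normal(size=30))}
        with pytest.warns(UserWarning, match="skipped"):
            result = class_ladder(data, profiles, "rank_sum")
        labels = [c.label for c in result.comparisons]
        assert "AP3_4_vs_AP2" not in labels and "AP2_vs_SP" in labels

    def test_missing_values_excluded(self):
        profiles = make_profiles([5, 5, 5, 5])
        data = {g: 1.0 for g in profiles["gene_id"]}
        data[profiles["gene_id"].iloc[0]] = float("nan")
        del data[profiles["gene_id"].iloc[1]]
        result = class_ladder(data, profiles, "rank_sum")
        assert result.class_summaries.set_index("class").loc["SP", "n"] == 3


def test_p_display_floor():
    assert p_display(1e-20) == "<2.2e-16"
    assert p_display(0.0123).startswith("0.0123")
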