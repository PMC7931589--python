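"""Conservation labels, intersection exact test, and rank-sum statistics."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from mirgrn.conservation import (
    classify_conservation,
    compare_conserved_vs_specific,
    intersection_tests,
    multiset_intersection_test,
    presence_matrix,
    venn_counts,
    wilcoxon_rank_sum,
)

GROUPS = ["fishes", "amphibians", "reptiles", "birds", "mammals"]


def presence_df(rows: dict) -> pd.DataFrame:
    return pd.DataFrame.from_dict(rows, orient="index", columns=GROUPS)


class TestPresenceAndLabels:
    def test_presence_from_flags_and_provenance(self):
        loci = pd.DataFrame({
            "locus_id": ["l1", "l2", "l3"],
            "species": ["fish1", "fish2", "frog1"],
            "family": ["mir-a", "mir-a", "mir-b"],
        })
        flags = pd.DataFrame(
            {"fish1": [True, False, False], "fish2": [False, False, False],
             "frog1": [False, False, False]},
            index=["l1", "l2", "l3"],
        )
        groups = {"fish1": "fishes", "fish2": "fishes", "frog1": "amphibians"}
        presence, prov = presence_matrix(loci, flags, groups)
        assert presence.loc["mir-a"].tolist() == [True, False]
        assert presence.loc["mir-b"].tolist() == [False, False]
        assert prov[("mir-a", "fishes")] == ["fish1"]

    def test_unmapped_species_is_config_error(self):
        loci = pd.DataFrame({"locus_id": ["l1"], "species": ["sp?"], "family": ["f"]})
        flags = pd.DataFrame({"sp?": [True]}, index=["l1"])
        with pytest.raises(ValueError, match="not mapped"):
            presence_matrix(loci, flags, {"other": "g"})

    @pytest.mark.parametrize("row,expected", [
        ((1, 1, 1, 1, 1), "conserved"),
        ((0, 0, 0, 0, 1), "group_specific:mammals"),
        ((1, 0, 1, 0, 0), "shared_subset"),
    ])
    def test_classification_rules(self, row, expected):
        labels = classify_conservation(presence_df({"f": [bool(v) for v in row]}))
        assert labels["f"] == expected

    def test_never_detected_family_excluded(self):
        labels = classify_conservation(presence_df({"f": [False] * 5}))
        assert "f" not in labels


class TestVenn:
    def test_exact_pattern_regions(self):
        df = presence_df({
            "f1": [True] * 5, "f2": [True] * 5,
            "f3": [False, True, False, False, False],
        })
        counts = venn_counts(df)
        assert counts[tuple(sorted(GROUPS))] == 2
        assert counts[("amphibians",)] == 1
        assert sum(counts.values()) == 3

    def test_regions_partition_detected_families(self, rng):
        data = {f"f{i}": list(rng.random(5) < 0.6) for i in range(40)}
        df = presence_df(data)
        counts = venn_counts(df)
        assert sum(counts.values()) == int(df.any(axis=1).sum())

    def test_order_invariance(self, rng):
        data = {f"f{i}": list(rng.random(5) < 0.5) for i in range(20)}
        df = presence_df(data)
        shuffled = df.sample(frac=1, random_state=0)[list(reversed(GROUPS))]
        assert venn_counts(df) == venn_counts(shuffled)

    def test_two_groups(self):
        df = pd.DataFrame([[True, False], [False, True], [True, True]],
                          columns=["a", "b"], index=["f1", "f2", "f3"])
        counts = venn_counts(df)
        assert counts[("a",)] == counts[("b",)] == counts[("a", "b")] == 1


def intersection_oracle(n: int, sizes: list[int], x: int) -> float:
    """P(|S1 ∩ ... ∩ Sk| >= x) by enumeration of subset configurations.

    By exchangeability the first subset is fixed to {0..n1-1}; the remaining
    subsets are enumerated exhaustively.
    """
    first = frozenset(range(sizes[0]))
    universe = range(n)
    total = hits = 0
    pools = [itertools.combinations(universe, s) for s in sizes[1:]]
    for rest in itertools.product(*pools):
        inter = first
        for s in rest:
            inter = inter & frozenset(s)
        total += 1
        hits += len(inter) >= x
    return hits / total if total else 1.0


class TestIntersectionTest:
    def test_closed_form_hypergeometric_tail(self):
        res = multiset_intersection_test([10, 10], 10, 20)
        assert res.p_value == pytest.approx(1 / comb(20, 10), rel=1e-12)

    def test_forced_full_intersection(self):
        assert multiset_intersection_test([6, 6, 6], 6, 6).p_value == 1.0

    def test_zero_overlap_tail_is_one(self):
        assert multiset_intersection_test([5, 7], 0, 20).p_value == 1.0

    @pytest.mark.parametrize("n,sizes,x", [
        (8, [4, 3], 2),
        (10, [5, 5], 3),
        (12, [6, 6], 4),
        (8, [4, 4, 3], 2),
        (10, [4, 3, 3], 1),
        (9, [5, 4, 3], 2),
    ])
    def test_matches_enumeration_oracle(self, n, sizes, x):
        res = multiset_intersection_test(sizes, x, n)
        assert abs(res.p_value - intersection_oracle(n, sizes, x)) < 1e-10

    def test_expected_overlap_independence_formula(self):
        res = multiset_intersection_test([10, 8], 4, 20)
        assert res.expected == pytest.approx(20 * (10 / 20) * (8 / 20))

    def test_set_larger_than_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            multiset_intersection_test([25, 5], 2, 20)

    def test_significance_flag_at_alpha(self):
        res = multiset_intersection_test([10, 10], 10, 20, alpha=0.005)
        assert res.significant

    def test_intersection_table_over_presence(self):
        df = pd.DataFrame(
            [[True, True], [True, True], [True, False], [False, True]],
            columns=["a", "b"], index=["f1", "f2", "f3", "f4"],
        )
        tbl = intersection_tests(df)
        row = tbl[tbl["combination"] == "a&b"].iloc[0]
        assert row["observed"] == 2
        # universe = 4 detected families, sizes 3 and 3
        assert row["expected"] == pytest.approx(4 * (3 / 4) * (3 / 4))


def u_enumeration_oracle(x, y, alternative):
    """Exact permutation p-value by brute enumeration of labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(
            1.0 if a > b else 0.5 if a == b else 0.0 for a in xs for b in ys
        )

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    p_greater = np.mean(us >= u_obs)
    p_less = np.mean(us <= u_obs)
    if alternative == "greater":
        return p_greater
    if alternative == "less":
        return p_less
    return min(1.0, 2 * min(p_greater, p_less))


class TestWilcoxon:
    def test_two_sided_enumeration_example(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.statistic == 0 and res.p_value == pytest.approx(2 / 6)

    def test_one_sided_enumeration_example(self):
        res = wilcoxon_rank_sum([5, 6, 7], [1, 2], "greater")
        assert res.statistic == 6 and res.p_value == pytest.approx(1 / 10)

    def test_identical_multisets_give_central_u(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.statistic == 4.5 and res.ties

    @pytest.mark.parametrize("n1,n2,alt", [
        (3, 4, "two-sided"), (5, 5, "greater"), (2, 6, "less"), (6, 6, "two-sided"),
    ])
    def test_exact_matches_enumeration_oracle(self, n1, n2, alt):
        rng = np.random.default_rng(n1 * 100 + n2)
        x, y = rng.normal(size=n1), rng.normal(size=n2)
        res = wilcoxon_rank_sum(x, y, alt)
        assert res.p_value == pytest.approx(u_enumeration_oracle(x, y, alt), abs=1e-12)

    @pytest.mark.parametrize("alt", ["two-sided", "greater", "less"])
    def test_large_sample_matches_scipy_asymptotic(self, alt):
        rng = np.random.default_rng(99)
        x = rng.normal(0.3, 1, size=30)
        y = np.round(rng.normal(0, 1, size=25), 1)  # induces ties
        res = wilcoxon_rank_sum(x, y, alt)
        ref = mannwhitneyu(x, y, alternative=alt.replace("-", "-"), method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError, match="nonempty"):
            wilcoxon_rank_sum([], [1.0])

    def test_u_bounded_by_n1_n2(self, rng):
        x, y = rng.normal(size=7), rng.normal(size=5)
        res = wilcoxon_rank_sum(x, y)
        assert 0 <= res.statistic <= 35


class TestCompareClasses:
    def test_single_family_per_class_exact_two_labelings(self):
        labels = {"c": "conserved", "s": "group_specific:fishes"}
        expr = {"c": 10.0, "s": 1.0}
        tgt = {"c": 5, "s": 1}
        expr_res, tgt_res = compare_conserved_vs_specific(labels, expr, tgt)
        assert expr_res.p_value == pytest.approx(0.5)
        assert tgt_res.p_value == pytest.approx(0.5)

    def test_empty_class_advises_skip(self):
        with pytest.raises(ValueError, match="skip"):
            compare_conserved_vs_specific({"c": "conserved"}, {"c": 1.0}, {"c": 1})
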