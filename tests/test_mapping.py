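from fractions import Fraction
from math import comb

import pandas as pd
import pytest
from scipy.stats import fisher_exact

from coexgalaxy import classify, mapping
from coexgalaxy.io import GeneSet


def brute_force_upper_tail(a, b, c, d):
    """Enumerate all tables with the same margins; sum P over x >= a."""
    n = a + b + c + d
    r, col = a + b, a + c
    total = Fraction(0)
    for x in range(max(0, r + col - n), min(r, col) + 1):
        if x >= a:
            total += Fraction(comb(r, x) * comb(n - r, col - x),
                              comb(n, col))
    return float(total)


def classification_of(pair_cats):
    """Build a classification frame from {(gi, gj): category}."""
    rows = [{"gene_i": gi, "gene_j": gj,
             "c_normal": 0.5, "c_disease": 0.5, "category": cat}
            for (gi, gj), cat in pair_cats.items()]
    return pd.DataFrame(rows)


class TestAnnotatedPairs:
    def test_pair_count_formula(self):
        genes = frozenset(f"G{i:02d}" for i in range(37))
        gs = GeneSet("T", "T", genes)
        pairs = mapping.annotated_pairs(gs, genes)
        assert len(pairs) == 37 * 36 // 2  # 666

    def test_two_genes_one_pair(self):
        gs = GeneSet("T", "T", frozenset({"B", "A"}))
        assert mapping.annotated_pairs(gs, {"A", "B", "C"}) == [("A", "B")]

    def test_restricted_to_analyzed_and_canonical(self):
        gs = GeneSet("T", "T", frozenset({"C", "A", "Z", "B"}))
        pairs = mapping.annotated_pairs(gs, {"A", "B", "C"})
        assert pairs == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_fewer_than_two_overlapping_genes_empty(self):
        gs = GeneSet("T", "T", frozenset({"X", "Y"}))
        assert mapping.annotated_pairs(gs, {"A"}) == []


class TestContingency:
    def test_all_common_gives_zero_table(self):
        cats = {("A", "B"): classify.COMMON_STRONG,
                ("A", "C"): classify.COMMON_WEAK}
        assert mapping.contingency(list(cats), classification_of(cats)) \
            == (0, 0, 0, 0)

    def test_counting_oracle_with_symmetry(self):
        cats = {
            ("A", "B"): classify.NORMAL_SPECIFIC_STRONG,
            ("A", "C"): classify.NORMAL_SPECIFIC_STRONG,
            ("A", "D"): classify.DISEASE_SPECIFIC_STRONG,
            ("B", "C"): classify.COMMON_STRONG,
            ("B", "D"): classify.COMMON_WEAK,
            ("C", "D"): classify.COMMON_STRONG,
        }
        a, b, c, d = mapping.contingency(list(cats), classification_of(cats))
        assert (a, b, c, d) == (2, 1, 1, 2)
        assert b == c and a == d  # specific-category equivalences

    def test_missing_pair_rejected(self):
        cats = {("A", "B"): classify.COMMON_STRONG}
        with pytest.raises(ValueError, match="absent"):
            mapping.contingency([("A", "Z")], classification_of(cats))

    def test_specific_plus_common_partition(self):
        import numpy as np
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(10)]
        from itertools import combinations
        cats = {p: rng.choice(classify.CATEGORIES)
                for p in combinations(genes, 2)}
        a, b, c, d = mapping.contingency(list(cats), classification_of(cats))
        n_common = sum(1 for v in cats.values()
                       if v in (classify.COMMON_STRONG, classify.COMMON_WEAK))
        assert (a + b) + n_common == len(cats)


class TestFisherOneSided:
    @pytest.mark.parametrize("table,expected", [
        ((186, 148, 148, 186), 0.002),
        ((137, 111, 111, 137), 0.012),
    ])
    def test_published_style_tables(self, table, expected):
        assert round(mapping.fisher_one_sided(*table), 3) == expected

    def test_symmetric_table_upper_tail_includes_mode(self):
        assert mapping.fisher_one_sided(5, 5, 5, 5) > 0.5

    @pytest.mark.parametrize("table", [
        (3, 1, 2, 4), (0, 5, 5, 0), (5, 0, 0, 5), (1, 1, 1, 1),
        (10, 3, 2, 9), (7, 7, 7, 7), (0, 0, 1, 0), (12, 0, 3, 8),
    ])
    def test_matches_bruteforce_and_scipy(self, table):
        p = mapping.fisher_one_sided(*table)
        assert p == pytest.approx(brute_force_upper_tail(*table), abs=1e-12)
        a, b, c, d = table
        assert p == pytest.approx(
            fisher_exact([[a, b], [c, d]], alternative="greater")[1],
            abs=1e-12)

    def test_tail_complement_identity(self):
        # p_upper + p_lower - P(observed) = 1 for any table
        a, b, c, d = 8, 3, 5, 9
        upper = mapping.fisher_one_sided(a, b, c, d)
        lower = mapping.fisher_one_sided(c, d, a, b)  # rows swapped
        exact = (brute_force_upper_tail(a, b, c, d)
                 - brute_force_upper_tail(a + 1, b - 1, c - 1, d + 1))
        assert upper + lower - exact == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            mapping.fisher_one_sided(0, 0, 0, 0)


class TestBonferroni:
    @pytest.mark.parametrize("p,m,expected", [
        (0.002, 11, 0.022),
        (0.012, 11, 0.132),
        (0.2, 11, 1.0),
    ])
    def test_multiplication_and_cap(self, p, m, expected):
        assert mapping.bonferroni(p, m) == pytest.approx(expected)

    @pytest.mark.parametrize("p_corr,expected", [
        (0.022, True), (0.132, False), (0.05, False)])
    def test_significance_strict(self, p_corr, expected):
        assert mapping.mapping_significance(p_corr) is expected


class TestMappingTests:
    def test_end_to_end_counts(self):
        from itertools import combinations
        genes = ["A", "B", "C", "D", "E"]
        cats = {}
        for i, p in enumerate(combinations(genes, 2)):
            cats[p] = (classify.NORMAL_SPECIFIC_STRONG if i % 3 == 0
                       else classify.COMMON_WEAK)
        classified = classification_of(cats)
        terms = [GeneSet("T1", "T1", frozenset({"A", "B", "C"})),
                 GeneSet("T2", "T2", frozenset({"A", "Z"}))]
        out = mapping.mapping_tests(terms, classified)
        t1 = out.set_index("term_id").loc["T1"]
        assert t1["n_annotated_pairs"] == 3
        assert t1["a"] == t1["d"] and t1["b"] == t1["c"]
        assert t1["p_bonferroni"] == pytest.approx(
            min(1.0, 2 * t1["p_one_sided"]))
        t2 = out.set_index("term_id").loc["T2"]
        assert t2["n_annotated_pairs"] == 0
        assert pd.isna(t2["p_one_sided"])
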