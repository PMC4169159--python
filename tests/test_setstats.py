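"""Gene-set overlap, Venn partitions, enrichment, and enumeration oracles."""

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biofilmscreen.setstats import (
    GeneSet,
    enrich_categories,
    hypergeom_overlap_test,
    overlap,
    venn3,
)


def enumeration_tail(N, K, n, k):
    """Independent oracle: P(X >= k) by direct summation of the pmf."""
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


class TestHypergeomOverlap:
    def test_five_of_five_in_ten(self):
        assert hypergeom_overlap_test(5, 5, 10, 5) == pytest.approx(1 / 252)

    def test_zero_overlap_upper_tail_is_one(self):
        assert hypergeom_overlap_test(5, 5, 20, 0) == pytest.approx(1.0)

    def test_matches_enumeration_for_all_small_universes(self):
        """Exhaustive agreement with the summation oracle for N ≤ 12."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        ours = hypergeom_overlap_test(K, n, N, k)
                        oracle = enumeration_tail(N, K, n, k)
                        assert ours == pytest.approx(oracle, rel=1e-10), (N, K, n, k)

    @pytest.mark.parametrize(
        "args", [(5, 5, 4, 0), (3, 3, 10, 4), (2, 9, 10, 0), (-1, 2, 10, 0)]
    )
    def test_infeasible_arguments(self, args):
        with pytest.raises(ValueError):
            hypergeom_overlap_test(*args)


class TestOverlap:
    def test_biofilm_invasive_overlap_is_69_percent(self):
        """71 biofilm-deficient genes, 49 also invasion-deficient → 69%."""
        biofilm = GeneSet("biofilm", [f"g{i}" for i in range(71)])
        invasive = GeneSet("invasive", [f"g{i}" for i in range(49)])
        res = overlap(biofilm, invasive, universe_size=4019)
        assert res.intersection_size == 49
        assert round(res.percent_of_a) == 69

    def test_identical_sets(self):
        a = GeneSet("a", ["x", "y", "z"])
        res = overlap(a, GeneSet("b", ["x", "y", "z"]), universe_size=10)
        assert res.percent_of_a == pytest.approx(100.0)
        assert res.intersection_size == 3

    def test_disjoint_sets(self):
        res = overlap(GeneSet("a", ["a1", "a2"]), GeneSet("b", ["b1", "b2"]), 100)
        assert res.intersection_size == 0
        assert res.percent_of_a == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_expected_overlap_cross_study(self):
        """69 biofilm+mat genes vs 655 mat genes in a 4019-gene library:
        chance expectation ≈ 11.24 genes."""
        a = GeneSet("biofilm_mat", [f"g{i}" for i in range(69)])
        b = GeneSet("mat_external", [f"g{i}" for i in range(38)] + [f"x{i}" for i in range(617)])
        res = overlap(a, b, universe_size=4019)
        assert res.expected_overlap == pytest.approx(69 * 655 / 4019, abs=1e-9)
        assert res.expected_overlap == pytest.approx(11.24, abs=0.01)
        assert res.intersection_size == 38

    def test_case_normalization(self):
        res = overlap(GeneSet("a", ["flo11"]), GeneSet("b", ["FLO11"]), 10)
        assert res.intersection_size == 1

    def test_universe_membership_enforced(self):
        universe = GeneSet("u", ["g1", "g2"])
        with pytest.raises(ValueError, match="absent"):
            overlap(GeneSet("a", ["g1", "g9"]), GeneSet("b", ["g2"]), 2, universe=universe)


class TestVenn3:
    def test_identical_sets_only_triple_region(self):
        s = GeneSet("s", ["a", "b", "c"])
        regions = venn3(s, s, s)
        assert regions["abc"] == 3
        assert all(regions[k] == 0 for k in ("a_only", "b_only", "c_only", "ab", "ac", "bc"))

    def test_pairwise_disjoint_only_singletons(self):
        regions = venn3(GeneSet("a", ["1"]), GeneSet("b", ["2", "3"]), GeneSet("c", ["4"]))
        assert (regions["a_only"], regions["b_only"], regions["c_only"]) == (1, 2, 1)
        assert regions["ab"] == regions["ac"] == regions["bc"] == regions["abc"] == 0

    def test_nested_phenotype_chain(self):
        """The screen's chain: 49 invasive ⊂ 69 mat ⊂ 71 biofilm."""
        genes = [f"g{i}" for i in range(71)]
        a = GeneSet("biofilm", genes)
        b = GeneSet("mat", genes[:69])
        c = GeneSet("invasive", genes[:49])
        regions = venn3(a, b, c)
        assert regions["abc"] == 49
        assert regions["ab"] == 20
        assert regions["a_only"] == 2
        assert regions["b_only"] == regions["c_only"] == regions["ac"] == regions["bc"] == 0

    @given(
        a=st.sets(st.integers(0, 15)),
        b=st.sets(st.integers(0, 15)),
        c=st.sets(st.integers(0, 15)),
    )
    @settings(deadline=None, derandomize=True)
    def test_regions_partition_the_union(self, a, b, c):
        ga, gb, gc = (GeneSet(l, {str(x) for x in s}) for l, s in (("a", a), ("b", b), ("c", c)))
        regions = venn3(ga, gb, gc)
        counts = [regions[k] for k in ("a_only", "b_only", "c_only", "ab", "ac", "bc", "abc")]
        assert all(v >= 0 for v in counts)
        assert sum(counts) == len(a | b | c)
        assert regions["a_only"] + regions["ab"] + regions["ac"] + regions["abc"] == len(a)


class TestEnrichment:
    def _universe(self, n):
        return GeneSet("universe", [f"g{i}" for i in range(n)])

    def test_perfect_category_matches_enumeration(self):
        """Set = exactly one 5-gene category in a 20-gene universe."""
        universe = self._universe(20)
        genes = GeneSet("hits", [f"g{i}" for i in range(5)])
        annotation = {f"g{i}": "catA" for i in range(5)}
        result = enrich_categories(genes, annotation, universe, correction="none")
        assert result.loc[0, "p_raw"] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_empty_category_overlap_p_one(self):
        universe = self._universe(10)
        genes = GeneSet("hits", ["g0", "g1"])
        annotation = {"g5": "catB"}
        result = enrich_categories(genes, annotation, universe, correction="none")
        assert result.loc[0, "p_raw"] == 1.0

    def test_identical_categories_collapsed_to_lowest_p(self):
        universe = self._universe(20)
        genes = GeneSet("hits", ["g0", "g1", "g2"])
        annotation = {f"g{i}": ["dup1", "dup2"] for i in range(3)}
        annotation["g10"] = ["other"]
        result = enrich_categories(genes, annotation, universe, correction="none")
        assert sorted(result["category"]) == ["dup1", "other"]

    def test_bonferroni_and_bh(self):
        universe = self._universe(30)
        genes = GeneSet("hits", [f"g{i}" for i in range(6)])
        annotation = {}
        for i in range(6):
            annotation[f"g{i}"] = [f"cat{i % 3}"]
        for i in range(6, 20):
            annotation[f"g{i}"] = [f"cat{i % 5}"]
        bonf = enrich_categories(genes, annotation, universe, correction="bonferroni")
        m = len(bonf)
        assert bonf["p_adjusted"].to_numpy() == pytest.approx(
            np.minimum(1.0, m * bonf["p_raw"].to_numpy())
        )
        bh = enrich_categories(genes, annotation, universe, correction="benjamini-hochberg")
        assert (bh["p_adjusted"].to_numpy() >= bh["p_raw"].to_numpy() - 1e-12).all()
        assert (np.diff(bh.sort_values("p_raw")["p_adjusted"].to_numpy()) >= -1e-12).all()

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            enrich_categories(GeneSet("e", []), {}, self._universe(5))

    def test_set_outside_universe_errors(self):
        with pytest.raises(ValueError, match="absent"):
            enrich_categories(GeneSet("s", ["zzz"]), {}, self._universe(5))
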