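"""Submodes, enrichment statistics, PEI, and the baseline methods."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from grade import (
    bh_adjust,
    extract_submodes,
    hypergeometric_enrichment,
    kmeans_baseline,
    pathway_enrichment_index,
    pca_baseline,
    read_gmt,
)


def exact_upper_tail(M, K, N, k):
    """P(overlap >= k) from the closed-form hypergeometric pmf."""
    total = math.comb(M, N)
    return sum(
        math.comb(K, j) * math.comb(M - K, N - j)
        for j in range(k, min(K, N) + 1)
    ) / total


@pytest.mark.filterwarnings("ignore:source rows deviate")
class TestExtractSubmodes:
    def test_signed_halves(self):
        S = np.array([[3.0, -2.5, 0.1]])
        sm = extract_submodes(S, ["g1", "g2", "g3"])
        pos, neg = sm[0], sm[1]
        assert pos.sign == "positive" and pos.genes == {"g1"}
        assert neg.sign == "negative" and neg.genes == {"g2"}

    def test_subthreshold_sources_give_empty_submodes(self):
        sm = extract_submodes(np.array([[1.0, -1.5, 0.0]]), list("abc"))
        assert sm[0].genes == set() and sm[1].genes == set()

    def test_threshold_boundary_inclusive(self):
        sm = extract_submodes(np.array([[2.0, -2.0, 0.0]]), list("abc"))
        assert sm[0].genes == {"a"} and sm[1].genes == {"b"}

    def test_non_unit_variance_warns(self):
        rng = np.random.default_rng(0)
        S = 5.0 * rng.standard_normal((1, 100))
        with pytest.warns(UserWarning, match="unit variance"):
            extract_submodes(S, [f"g{i}" for i in range(100)])


class TestHypergeometricEnrichment:
    def test_worked_toy_example(self):
        # universe 10, set 5, query 4, overlap 4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        universe = {f"g{i}" for i in range(10)}
        annotation = {"path": [f"g{i}" for i in range(5)]}
        query = {"g0", "g1", "g2", "g3"}
        table = hypergeometric_enrichment(query, universe, annotation)
        assert table.loc[0, "p"] == pytest.approx(5 / 210)

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        annotation = {"path": ["g0", "g1"]}
        table = hypergeometric_enrichment({"g8", "g9"}, universe, annotation)
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_query_equal_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(6)}
        annotation = {"path": ["g0", "g1", "g2"]}
        table = hypergeometric_enrichment(universe, universe, annotation)
        assert table.loc[0, "overlap"] == 3
        assert table.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration_small_universes(self):
        for M in (4, 8, 12):
            universe = {f"g{i}" for i in range(M)}
            for K, N in itertools.product(range(2, M + 1), range(1, M + 1)):
                annotation = {"s": [f"g{i}" for i in range(K)]}
                query = {f"g{i}" for i in range(N)}
                k = len(set(annotation["s"]) & query)
                table = hypergeometric_enrichment(query, universe, annotation)
                assert table.loc[0, "p"] == pytest.approx(
                    exact_upper_tail(M, K, N, k), abs=1e-12)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeometric_enrichment({"x"}, {"a", "b"}, {"s": ["a", "b"]})

    def test_empty_annotation_gives_empty_table(self):
        table = hypergeometric_enrichment({"a"}, {"a", "b"}, {})
        assert len(table) == 0


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_value_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_equal_values_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.1, 0.1, 0.1]), [0.1, 0.1, 0.1])

    def test_matches_manual_step_up_on_random_input(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        # independent oracle: literal step-up rule
        order = np.argsort(p)
        n = len(p)
        stepped = p[order] * n / (np.arange(n) + 1)
        adj_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_monotone_in_raw_p_rank(self):
        rng = np.random.default_rng(1)
        p = np.sort(rng.uniform(size=40))
        adj = bh_adjust(p)
        assert np.all(np.diff(adj) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestPathwayEnrichmentIndex:
    def _toy(self):
        universe = {f"g{i}" for i in range(20)}
        annotation = {
            "hit": [f"g{i}" for i in range(5)],       # enriched in submode 1
            "miss1": [f"g{i}" for i in range(10, 15)],
            "miss2": [f"g{i}" for i in range(15, 20)],
        }
        submodes = [{f"g{i}" for i in range(5)}, {"g10", "g17"}]
        return submodes, universe, annotation

    def test_constructed_one_of_three(self):
        submodes, universe, annotation = self._toy()
        res = pathway_enrichment_index(submodes, universe, annotation)
        assert res.total_tested == 3
        assert res.significant_union == {"hit"}
        assert res.pei == pytest.approx(1 / 3)

    def test_no_significant_pathway_gives_zero(self):
        universe = {f"g{i}" for i in range(8)}
        annotation = {"a": ["g0", "g1"], "b": ["g2", "g3"]}
        res = pathway_enrichment_index([{"g7"}], universe, annotation)
        assert res.pei == 0.0

    def test_all_significant_gives_one(self):
        universe = {f"g{i}" for i in range(30)}
        annotation = {"a": [f"g{i}" for i in range(4)],
                      "b": [f"g{i}" for i in range(4, 8)]}
        res = pathway_enrichment_index(
            [{f"g{i}" for i in range(4)}, {f"g{i}" for i in range(4, 8)}],
            universe, annotation)
        assert res.pei == 1.0

    def test_monotone_when_adding_submodes(self):
        submodes, universe, annotation = self._toy()
        small = pathway_enrichment_index(submodes[:1], universe, annotation)
        large = pathway_enrichment_index(submodes, universe, annotation)
        assert large.pei >= small.pei

    def test_disjoint_annotation_is_error(self):
        with pytest.raises(ValueError, match="PEI"):
            pathway_enrichment_index([{"a"}], {"a", "b"}, {"s": ["x", "y"]})


class TestPcaBaseline:
    def test_dominant_direction_captured(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(500)
        X = np.vstack([base * (4 - i) + 0.01 * rng.standard_normal(500)
                       for i in range(4)])
        res = pca_baseline(X)
        assert res.explained_variance_ratio[0] > 0.99

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(1)
        res = pca_baseline(rng.standard_normal((4, 300)))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_white_data_spreads_variance_evenly(self):
        rng = np.random.default_rng(2)
        res = pca_baseline(rng.standard_normal((4, 20000)))
        assert np.all(res.explained_variance_ratio < 0.30)

    def test_components_have_unit_variance_and_reconstruct(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((4, 200)) * np.array([[3.0], [2.0], [1.0], [0.5]])
        res = pca_baseline(X)
        np.testing.assert_allclose(res.S.std(axis=1, ddof=1), 1.0, atol=1e-8)
        Xc = X - X.mean(axis=1, keepdims=True)
        np.testing.assert_allclose(res.A @ res.S, Xc, atol=1e-8)


class TestKmeansBaseline:
    def _blobs(self, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 0.2, size=(30, 4)) + np.array([5, 5, 0, 0])
        b = rng.normal(0.0, 0.2, size=(30, 4)) + np.array([0, 0, 5, 5])
        return pd.DataFrame(np.vstack([a, b]),
                            index=[f"g{i}" for i in range(60)])

    def test_separated_blobs_recovered_up_to_label_swap(self):
        X = self._blobs()
        res = kmeans_baseline(X, k=2, top_frac=1.0, seed=0)
        by_gene = dict(zip(res.genes, res.labels))
        first = {by_gene[f"g{i}"] for i in range(30)}
        second = {by_gene[f"g{i}"] for i in range(30, 60)}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_same_seed_reproducible(self):
        X = self._blobs()
        r1 = kmeans_baseline(X, k=2, top_frac=1.0, seed=3)
        r2 = kmeans_baseline(X, k=2, top_frac=1.0, seed=3)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_full_fraction_keeps_all_genes(self):
        X = self._blobs()
        res = kmeans_baseline(X, k=2, top_frac=1.0, seed=0)
        assert len(res.genes) == len(X)

    def test_variance_filter_keeps_top_fraction(self):
        X = self._blobs()
        res = kmeans_baseline(X, k=2, top_frac=0.5, seed=0)
        assert len(res.genes) == 30

    def test_too_many_clusters_rejected(self):
        X = self._blobs()
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_baseline(X, k=40, top_frac=0.5, seed=0)


class TestReadGmt:
    def test_basic_records(self):
        lines = ["setA\tdesc\tg1\tg2\tg3\n", "setB\t-\tg4\tg5\n"]
        sets = read_gmt(lines)
        assert sets == {"setA": ["g1", "g2", "g3"], "setB": ["g4", "g5"]}

    def test_short_record_rejected(self):
        with pytest.raises(ValueError, match="line 1"):
            read_gmt(["setA\tdesc\n"])

    def test_duplicate_name_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(["s\td\tg1\n", "s\td\tg2\n"])
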