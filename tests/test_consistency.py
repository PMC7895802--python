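import numpy as np
import pandas as pd
import pytest

from agemeta.consistency import (
    ConsistencyResult,
    bh_adjust,
    compare_gene_between_groups,
    leading_edge_hubs,
    median_rank_test,
    null_median_ranks,
    rank_terms_within_intervention,
    shared_opposite_terms,
)
from agemeta.enrich import EnrichmentResult, EnrichmentScoreMatrix
from agemeta.exceptions import ConfigError, DataError, InsufficientDataError

from ._oracles import exact_two_sided_median_pvalue
from .conftest import make_metadata


def es_matrix(scores: pd.DataFrame) -> EnrichmentScoreMatrix:
    return EnrichmentScoreMatrix(scores=scores, dataset_scores=scores, provenance={})


class TestRankTerms:
    def test_simple_ordering(self):
        ranks = rank_terms_within_intervention(pd.Series([3.2, -1.1, 0.5],
                                                         index=list("abc")))
        assert list(ranks) == [1.0, 3.0, 2.0]

    def test_ties_get_average_ranks(self):
        ranks = rank_terms_within_intervention(pd.Series([2.0, 2.0], index=list("ab")))
        assert list(ranks) == [1.5, 1.5]

    def test_missing_scores_excluded(self):
        ranks = rank_terms_within_intervention(
            pd.Series([1.0, np.nan, 3.0], index=list("abc")))
        assert np.isnan(ranks["b"]) and ranks["c"] == 1.0 and ranks["a"] == 2.0

    def test_single_score_is_error(self):
        with pytest.raises(DataError):
            rank_terms_within_intervention(pd.Series([1.0], index=["a"]))


class TestMedianRankTest:
    def test_extreme_term_at_top_approaches_exact_tail(self):
        # T=3, I=2, term ranked (1,1): exact null over 9 rank pairs gives
        # P(median <= 1) = 1/9; the two-sided p approaches 2/9
        scores = pd.DataFrame(
            {"iv1": [3.0, 2.0, 1.0], "iv2": [3.0, 2.0, 1.0]},
            index=["A", "B", "C"],
        )
        res = median_rank_test(es_matrix(scores), ["iv1", "iv2"], n_random=100_000,
                               seed=0)
        top = next(r for r in res if r.term_id == "A")
        assert top.median_rank == 1.0
        assert top.direction == 1
        assert top.pvalue == pytest.approx(2 / 9, abs=0.01)

    def test_bottom_term_has_down_direction_and_smallest_p(self):
        scores = pd.DataFrame(
            {"iv1": [0.1, 0.2, 0.3, -5.0], "iv2": [0.3, 0.1, 0.2, -6.0],
             "iv3": [0.2, 0.3, 0.1, -4.0]},
            index=list("ABCD"),
        )
        res = median_rank_test(es_matrix(scores), ["iv1", "iv2", "iv3"],
                               n_random=50_000, seed=1)
        bottom = next(r for r in res if r.term_id == "D")
        assert bottom.direction == -1
        assert bottom.median_rank == 4.0
        assert bottom.pvalue == min(r.pvalue for r in res)

    def test_identical_rank_vectors_get_identical_results(self):
        scores = pd.DataFrame(
            {"iv1": [5.0, 5.0, 1.0, 0.5], "iv2": [4.0, 4.0, 0.5, 1.0]},
            index=list("ABCD"),
        )
        res = {r.term_id: r for r in median_rank_test(
            es_matrix(scores), ["iv1", "iv2"], n_random=20_000, seed=2)}
        assert res["A"].pvalue == res["B"].pvalue
        assert res["A"].direction == res["B"].direction

    def test_requires_two_interventions(self):
        scores = pd.DataFrame({"iv1": [1.0, 2.0]}, index=["A", "B"])
        with pytest.raises(InsufficientDataError):
            median_rank_test(es_matrix(scores), ["iv1"])

    def test_monte_carlo_null_matches_exhaustive_enumeration(self):
        # T=4, I=3: exact null over 4^3 = 64 rank tuples
        rng = np.random.default_rng(3)
        null = null_median_ranks(4, 3, 100_000, rng)
        for obs in (1.0, 1.5, 2.0, 2.5, 3.0, 4.0):
            mc = np.mean(null <= obs)
            _, _ = obs, mc
            exact = np.mean(
                np.array([float(np.median(t)) for t in
                          __import__("itertools").product(range(1, 5), repeat=3)])
                <= obs)
            sd = np.sqrt(exact * (1 - exact) / 100_000)
            assert abs(mc - exact) <= 3 * sd + 1e-9

    def test_two_sided_p_matches_oracle_on_tiny_matrix(self):
        scores = pd.DataFrame(
            {"iv1": [4.0, 3.0, 2.0, 1.0], "iv2": [4.0, 2.0, 3.0, 1.0],
             "iv3": [3.0, 4.0, 1.0, 2.0]},
            index=list("ABCD"),
        )
        res = {r.term_id: r for r in median_rank_test(
            es_matrix(scores), ["iv1", "iv2", "iv3"], n_random=100_000, seed=4)}
        ranks = {"A": [1, 1, 2], "B": [2, 3, 1], "C": [3, 2, 4], "D": [4, 4, 3]}
        for term, rk in ranks.items():
            _, p_exact = exact_two_sided_median_pvalue(4, rk)
            sd = 2 * np.sqrt(max(p_exact, 1e-6) * (1 - p_exact / 2) / 100_000)
            assert abs(res[term].pvalue - p_exact) <= 3 * sd + 4 / 100_001


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.05, 0.05, 0.05]), [0.05] * 3)

    def test_permutation_invariance(self, rng):
        p = rng.uniform(0.001, 1, 25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_monotone_in_sorted_order(self, rng):
        p = np.sort(rng.uniform(0.0001, 1, 40))
        q = bh_adjust(p)
        assert np.all(np.diff(q) >= -1e-12)
        assert np.all(q >= p)

    def test_domain_error(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 0.0])


def _cres(term, group, q, direction):
    return ConsistencyResult(term_id=term, group=group, median_rank=1.0,
                             pvalue=min(q, 1.0), qvalue=q, direction=direction,
                             n_interventions=4)


class TestSharedOpposite:
    def test_four_way_partition(self):
        long_res = [_cres("A", "long", 0.01, +1), _cres("B", "long", 0.01, +1),
                    _cres("C", "long", 0.01, +1), _cres("D", "long", 0.2, +1)]
        short_res = [_cres("A", "short", 0.01, -1), _cres("B", "short", 0.01, +1),
                     _cres("C", "short", 0.2, -1), _cres("D", "short", 0.2, -1)]
        part = shared_opposite_terms(long_res, short_res, fdr=0.05)
        assert part["shared_opposite"] == ["A"]
        assert part["shared_same"] == ["B"]
        assert part["long_specific"] == ["C"]
        assert part["neither"] == ["D"]

    def test_disjoint_catalogues_rejected(self):
        with pytest.raises(DataError):
            shared_opposite_terms([_cres("A", "long", 0.01, 1)],
                                  [_cres("B", "short", 0.01, 1)])


def _le_result(term, genes):
    return EnrichmentResult(term_id=term, es_stat=0.5, pvalue=0.01, direction=1,
                            score=2.0, leading_edge=frozenset(genes), n_genes=10)


class TestHubGenes:
    def _setup(self, per_iv_terms_with_gene):
        """One dataset per intervention; gene 'hub' sits in the given terms."""
        metadata, dataset_results = {}, {}
        for i, terms in enumerate(per_iv_terms_with_gene):
            iv = f"iv{i}"
            ds = f"{iv}_ds"
            metadata[ds] = make_metadata(ds, iv)
            dataset_results[ds] = {
                t: _le_result(t, {"hub", f"filler{t}"} if t in terms else {f"filler{t}"})
                for t in ("T1", "T2", "T3")
            }
        return dataset_results, metadata

    def test_gene_in_two_terms_everywhere_is_hub(self):
        results, meta = self._setup([("T1", "T2")] * 4)
        report = leading_edge_hubs(results, meta, [f"iv{i}" for i in range(4)],
                                   ["T1", "T2", "T3"])
        assert [h.gene_id for h in report.genes] == ["hub"]
        assert report.genes[0].interventions_supporting == 4
        assert report.genes[0].terms_led == frozenset({"T1", "T2"})

    def test_single_term_gene_is_not_hub(self):
        results, meta = self._setup([("T1",)] * 4)
        report = leading_edge_hubs(results, meta, [f"iv{i}" for i in range(4)],
                                   ["T1", "T2", "T3"])
        assert report.genes == []

    def test_support_below_half_of_interventions_is_not_hub(self):
        # two terms in 1 of 4 interventions: 1 < ceil(4/2) = 2
        results, meta = self._setup([("T1", "T2"), (), (), ()])
        report = leading_edge_hubs(results, meta, [f"iv{i}" for i in range(4)],
                                   ["T1", "T2", "T3"])
        assert report.genes == []

    def test_empty_focal_set_rejected(self):
        results, meta = self._setup([("T1",)] * 2)
        with pytest.raises(ConfigError):
            leading_edge_hubs(results, meta, ["iv0", "iv1"], [])


class TestCompareGene:
    def _matrix(self, long_vals, short_vals):
        cols, meta = {}, {}
        for i, v in enumerate(long_vals):
            ds = f"L{i}"
            cols[ds] = [v]
            meta[ds] = make_metadata(ds, f"liv{i}", group="long")
        for i, v in enumerate(short_vals):
            ds = f"S{i}"
            cols[ds] = [v]
            meta[ds] = make_metadata(ds, f"siv{i}", group="short")
        return pd.DataFrame(cols, index=["gene1"]), meta

    def test_exact_extreme_split(self):
        m, meta = self._matrix([1, 2, 3], [4, 5, 6])
        p, medians = compare_gene_between_groups(m, meta, "gene1")
        assert p == pytest.approx(0.1)
        assert medians == {"long": 2.0, "short": 5.0}

    def test_identical_groups_give_p_one(self):
        m, meta = self._matrix([1, 2, 3], [1, 2, 3])
        p, _ = compare_gene_between_groups(m, meta, "gene1")
        assert p == pytest.approx(1.0)

    def test_single_dataset_group_rejected(self):
        m, meta = self._matrix([1.0], [2.0, 3.0])
        with pytest.raises(InsufficientDataError):
            compare_gene_between_groups(m, meta, "gene1")

    def test_absent_gene_rejected(self):
        m, meta = self._matrix([1, 2], [3, 4])
        with pytest.raises(DataError):
            compare_gene_between_groups(m, meta, "nope")
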