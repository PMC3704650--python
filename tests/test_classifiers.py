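"""Score integration: naive Bayes and additive classifiers, ranking, decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenologs import (
    WeightingSpec,
    build_matrix_set,
    decompose,
    fraction_f,
    predict,
    score_additive,
    score_naive_bayes,
    weight_from_measure,
)
from tests.conftest import one_to_one_config


class TestFractionF:
    @pytest.mark.parametrize("v,n,expected", [(2, 4, 0.5), (0, 5, 0.0), (3, 3, 1.0)])
    def test_ratio(self, v, n, expected):
        assert fraction_f(v, n) == expected

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            fraction_f(0, 0)


class TestWeightFromMeasure:
    @pytest.mark.parametrize(
        "value,measure,expected",
        [
            (0.01, "hypergeom", 0.99),
            (-0.3, "pearson", 0.0),
            (0.7, "pearson", 0.7),
            (0.4, "tanimoto", 0.4),
            (0.4, "cosine", 0.4),
            (3.0, "euclidean", 0.25),
            (0.0, "manhattan", 1.0),
        ],
    )
    def test_mapping(self, value, measure, expected):
        assert weight_from_measure(value, measure) == pytest.approx(expected)

    def test_unknown_measure(self):
        with pytest.raises(KeyError):
            weight_from_measure(0.5, "mahalanobis")


class TestScoreAdditive:
    def test_worked_example(self):
        scores = score_additive(
            [(frozenset({"g1", "g2"}), 0.5), (frozenset({"g2", "g3"}), 0.25)]
        )
        assert scores == {"g1": 0.5, "g2": 0.75, "g3": 0.25}

    def test_all_zero_weights(self):
        scores = score_additive([(frozenset({"g1"}), 0.0)])
        assert scores == {"g1": 0.0}

    def test_single_neighbor(self):
        scores = score_additive([(frozenset({"g1", "g2"}), 0.3)])
        assert scores == {"g1": 0.3, "g2": 0.3}

    @given(
        st.lists(
            st.tuples(
                st.frozensets(st.integers(0, 8).map(str), max_size=9),
                st.floats(0, 1),
            ),
            max_size=6,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_double_loop_oracle_and_linearity(self, neighbors):
        scores = score_additive(neighbors)
        elements = set().union(*(c for c, _ in neighbors)) if neighbors else set()
        for el in elements:
            brute = sum(w for col, w in neighbors if el in col)
            assert scores[el] == pytest.approx(brute, rel=1e-12)
        doubled = score_additive([(c, 2 * w) for c, w in neighbors])
        for el in elements:
            assert doubled[el] == pytest.approx(2 * scores[el], rel=1e-12)


class TestScoreNaiveBayes:
    def test_single_neighbor_equals_fw(self):
        scores = score_naive_bayes([(frozenset({"g"}), 0.5, 0.4)])
        assert scores["g"] == pytest.approx(0.2)

    def test_two_neighbors_closed_form(self):
        scores = score_naive_bayes(
            [(frozenset({"g"}), 0.5, 0.4), (frozenset({"g"}), 0.4, 0.5)]
        )
        assert scores["g"] == pytest.approx(1 - 0.8**2)

    def test_uncovered_element_scores_zero(self):
        scores = score_naive_bayes([(frozenset({"g"}), 0.5, 0.4)])
        assert scores.get("h", 0.0) == 0.0

    def test_adding_neighbor_strictly_increases(self):
        base = score_naive_bayes([(frozenset({"g"}), 0.5, 0.4)])
        more = score_naive_bayes(
            [(frozenset({"g"}), 0.5, 0.4), (frozenset({"g"}), 0.1, 0.1)]
        )
        assert more["g"] > base["g"]

    @given(
        st.lists(
            st.tuples(st.floats(0.001, 1), st.floats(0.001, 1)), min_size=1, max_size=8
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_scores_in_unit_interval(self, fws):
        scores = score_naive_bayes([(frozenset({"g"}), f, w) for f, w in fws])
        assert 0.0 <= scores["g"] <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_naive_bayes([(frozenset({"g"}), 1.5, 0.4)])


class TestPredict:
    def test_ranks_sum_to_triangular_number(self, small_matrix_set):
        for pid in ("human:M0:P0", "human:M1:P1", "human:BG:P0"):
            plist = predict(pid, small_matrix_set, WeightingSpec(k=10))
            P = len(plist)
            assert plist.ranks.sum() == pytest.approx(P * (P + 1) / 2)

    def test_scores_non_increasing(self, small_matrix_set):
        plist = predict("human:M0:P0", small_matrix_set, WeightingSpec(k=10))
        scores = [p.score for p in plist.predictions]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_naive_bayes_scores_in_unit_interval(self, small_matrix_set):
        plist = predict(
            "human:M0:P0", small_matrix_set, WeightingSpec(k=10, classifier="naive_bayes")
        )
        assert all(0.0 <= p.score <= 1.0 for p in plist.predictions)

    def test_equal_scores_share_mean_rank(self, small_matrix_set):
        plist = predict("human:M0:P0", small_matrix_set, WeightingSpec(k=10))
        by_score: dict[float, list[float]] = {}
        for pred, rank in zip(plist.predictions, plist.ranks):
            by_score.setdefault(pred.score, []).append(rank)
        for ranks in by_score.values():
            assert len(set(ranks)) == 1

    def test_known_genes_flagged(self, small_matrix_set):
        plist = predict("human:M0:P0", small_matrix_set, WeightingSpec(k=10))
        known_genes = small_matrix_set.within.column("human:M0:P0")
        flagged = {p.gene_id for p in plist.predictions if p.known}
        assert known_genes <= flagged

    def test_unknown_phenotype_raises(self, small_matrix_set):
        with pytest.raises(KeyError):
            predict("nope", small_matrix_set)

    def test_additive_score_equals_contribution_sum(self, small_matrix_set):
        plist = predict(
            "human:M0:P0", small_matrix_set, WeightingSpec(k=10, classifier="additive")
        )
        for p in plist.predictions:
            assert p.score == pytest.approx(sum(c.term for c in p.contributions))

    def test_one_to_one_frameworks_agree(self):
        """Under strict 1:1 orthology, gene-based and orthogroup-based
        pipelines must produce identical prediction lists."""
        from phenologs import generate

        data = generate(one_to_one_config(seed=5))
        spec = WeightingSpec(k=5)
        og = build_matrix_set(data.associations, data.orthology, "human",
                              framework="orthogroup")
        gb = build_matrix_set(data.associations, data.orthology, "human",
                              framework="gene")
        for pid in ("human:M0:P0", "human:M1:P2"):
            a = predict(pid, og, spec)
            b = predict(pid, gb, spec)
            assert [p.gene_id for p in a.predictions] == [p.gene_id for p in b.predictions]
            np.testing.assert_allclose(
                [p.score for p in a.predictions],
                [p.score for p in b.predictions],
                atol=1e-12,
            )
            np.testing.assert_array_equal(a.ranks, b.ranks)


class TestDecompose:
    def test_rows_sum_to_additive_scores(self, small_matrix_set):
        plist = predict(
            "human:M0:P0", small_matrix_set, WeightingSpec(k=10, classifier="additive")
        )
        table = decompose(plist, top_n_phenotypes=3)
        scores = {p.gene_id: p.score for p in plist.predictions}
        for gene, row in table.iterrows():
            assert row.sum() == pytest.approx(scores[gene])
        assert table.attrs["additive"] is True

    def test_no_remainder_when_top_n_covers_k(self, small_matrix_set):
        plist = predict(
            "human:M0:P0", small_matrix_set, WeightingSpec(k=5, classifier="additive")
        )
        table = decompose(plist, top_n_phenotypes=50)
        assert not any("below top-" in c for c in table.columns)

    def test_single_neighbor_gene_single_column(self, small_matrix_set):
        plist = predict(
            "human:M0:P0", small_matrix_set, WeightingSpec(k=10, classifier="additive")
        )
        table = decompose(plist, top_n_phenotypes=20)
        for gene, row in table.iterrows():
            pred = next(p for p in plist.predictions if p.gene_id == gene)
            if len(pred.contributions) == 1:
                assert (row > 0).sum() == 1
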