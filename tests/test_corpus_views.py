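"""Indexing, profile aggregation, IDF weighting, merging and concept mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mvgene.corpus import Corpus, SynonymTable, Vocabulary, index_corpus, no_voc_vocabulary
from mvgene.views import (
    aggregate_gene_profiles,
    build_view,
    idf_transform,
    map_concepts,
    merge_views,
)


def _corpus(docs, gmap):
    return Corpus(
        documents=docs, gene_doc_map={g: frozenset(d) for g, d in gmap.items()}
    )


class TestIndexCorpus:
    def test_counts_only_vocabulary_terms(self):
        corpus = _corpus({"d1": {"muscle": 3, "zzz": 1}}, {"g1": {"d1"}})
        dt = index_corpus(corpus, Vocabulary("v", ("muscle", "heart")))
        assert dt.counts.toarray().tolist() == [[3.0, 0.0]]

    def test_disjoint_vocabulary_gives_zero_matrix(self):
        corpus = _corpus({"d1": {"a": 2}, "d2": {"b": 1}}, {"g1": {"d1", "d2"}})
        dt = index_corpus(corpus, Vocabulary("v", ("x", "y", "z")))
        assert dt.counts.nnz == 0

    def test_shared_term_column_identical_across_vocabularies(self):
        corpus = _corpus(
            {"d1": {"heart": 2}, "d2": {"heart": 5, "lung": 1}}, {"g": {"d1", "d2"}}
        )
        c1 = index_corpus(corpus, Vocabulary("a", ("heart", "lung")))
        c2 = index_corpus(corpus, Vocabulary("b", ("kidney", "heart")))
        col1 = c1.counts.toarray()[:, 0]
        col2 = c2.counts.toarray()[:, 1]
        np.testing.assert_array_equal(col1, col2)

    def test_vocabulary_validation(self):
        with pytest.raises(ValueError):
            Vocabulary("v", ())
        with pytest.raises(ValueError):
            Vocabulary("v", ("a", "a"))


class TestAggregate:
    def test_single_document_gene_equals_document_row(self):
        corpus = _corpus({"d1": {"a": 4, "b": 1}}, {"g1": {"d1"}})
        dt = index_corpus(corpus, Vocabulary("v", ("a", "b")))
        view = aggregate_gene_profiles(dt, corpus.gene_doc_map)
        np.testing.assert_array_equal(view.weights, [[4.0, 1.0]])

    def test_mean_of_two_documents(self):
        corpus = _corpus({"d1": {"a": 2}, "d2": {"b": 2}}, {"g1": {"d1", "d2"}})
        dt = index_corpus(corpus, Vocabulary("v", ("a", "b")))
        view = aggregate_gene_profiles(dt, corpus.gene_doc_map)
        np.testing.assert_array_equal(view.weights, [[1.0, 1.0]])

    def test_gene_without_documents_is_flagged_zero_row(self):
        corpus = _corpus({"d1": {"a": 1}}, {"g1": {"d1"}, "g2": set()})
        dt = index_corpus(corpus, Vocabulary("v", ("a",)))
        view = aggregate_gene_profiles(dt, corpus.gene_doc_map)
        assert view.zero_doc_genes == {"g2"}
        i = view.gene_ids.index("g2")
        assert not view.weights[i].any()

    def test_gene_order_permutation_invariance(self):
        docs = {"d1": {"a": 1}, "d2": {"a": 3, "b": 1}}
        fwd = _corpus(docs, {"g1": {"d1"}, "g2": {"d2"}})
        rev = _corpus(docs, {"g2": {"d2"}, "g1": {"d1"}})
        vocab = Vocabulary("v", ("a", "b"))
        v1 = aggregate_gene_profiles(index_corpus(fwd, vocab), fwd.gene_doc_map)
        v2 = aggregate_gene_profiles(index_corpus(rev, vocab), rev.gene_doc_map)
        assert v1.gene_ids == v2.gene_ids
        np.testing.assert_array_equal(v1.weights, v2.weights)


class TestIdf:
    def _view_and_dt(self):
        docs = {f"d{i}": {"common": 1} for i in range(10)}
        docs["d0"]["rare"] = 2
        corpus = _corpus(docs, {"g1": {"d0"}, "g2": {"d1"}})
        dt = index_corpus(corpus, Vocabulary("v", ("common", "rare", "absent")))
        return aggregate_gene_profiles(dt, corpus.gene_doc_map), dt

    def test_ubiquitous_term_column_zeroed(self):
        view, dt = self._view_and_dt()
        idf = idf_transform(view, dt)
        j = idf.term_ids.index("common")
        assert not idf.weights[:, j].any()

    def test_rare_term_weight_is_log_d_over_df(self):
        view, dt = self._view_and_dt()
        idf = idf_transform(view, dt)
        j = idf.term_ids.index("rare")
        i = idf.gene_ids.index("g1")
        assert idf.weights[i, j] == pytest.approx(2 * np.log(10.0))

    def test_unseen_term_gets_zero_weight_and_zero_rows_stay_zero(self):
        view, dt = self._view_and_dt()
        idf = idf_transform(view, dt)
        j = idf.term_ids.index("absent")
        assert not idf.weights[:, j].any()


class TestMergeAndConcepts:
    def test_disjoint_vocabularies_merge_to_sum_of_sizes(self):
        corpus = _corpus({"d": {"a": 1, "x": 1}}, {"g": {"d"}})
        merged = merge_views(
            [Vocabulary("u", ("a", "b")), Vocabulary("w", ("x", "y"))], corpus
        )
        assert merged.n_terms == 4

    def test_identical_vocabularies_merge_to_single_view(self):
        corpus = _corpus({"d": {"a": 2, "b": 1}}, {"g": {"d"}})
        vocab = Vocabulary("u", ("a", "b"))
        merged = merge_views([vocab, vocab], corpus)
        single = build_view(corpus, vocab)
        np.testing.assert_allclose(merged.weights, single.weights)

    def test_union_size_bounded_by_sum(self):
        v1 = Vocabulary("u", ("a", "b", "c"))
        v2 = Vocabulary("w", ("c", "d"))
        corpus = _corpus({"d": {"a": 1}}, {"g": {"d"}})
        merged = merge_views([v1, v2], corpus)
        assert merged.n_terms == 4 < len(v1) + len(v2)

    def test_synonym_columns_sum(self):
        corpus = _corpus({"d": {"a": 2, "b": 3}}, {"g": {"d"}})
        view = build_view(corpus, Vocabulary("v", ("a", "b")), weighting="count")
        mapped = map_concepts(view, SynonymTable({"a": "c1", "b": "c1"}))
        assert mapped.term_ids == ("c1",)
        np.testing.assert_array_equal(mapped.weights, [[5.0]])

    def test_identity_synonyms_change_nothing(self):
        corpus = _corpus({"d": {"a": 2, "b": 3}}, {"g": {"d"}})
        view = build_view(corpus, Vocabulary("v", ("a", "b")), weighting="count")
        mapped = map_concepts(view, SynonymTable({}))
        assert set(mapped.term_ids) == {"a", "b"}
        np.testing.assert_array_equal(
            mapped.weights[:, np.argsort(mapped.term_ids)],
            view.weights[:, np.argsort(view.term_ids)],
        )

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 5), min_size=3, max_size=3))
    def test_concept_mapping_conserves_row_totals(self, counts):
        corpus = _corpus(
            {"d": {t: c for t, c in zip("abc", counts) if c}}, {"g": {"d"}}
        )
        view = build_view(corpus, Vocabulary("v", ("a", "b", "c")), weighting="count")
        mapped = map_concepts(view, SynonymTable({"a": "k", "c": "k"}))
        assert mapped.weights.sum() == pytest.approx(view.weights.sum())

    def test_no_voc_vocabulary_is_corpus_token_set(self):
        corpus = _corpus({"d1": {"a": 1, "b": 2}, "d2": {"c": 1}}, {"g": {"d1", "d2"}})
        assert set(no_voc_vocabulary(corpus).terms) == {"a", "b", "c"}
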