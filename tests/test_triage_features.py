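"""Triage features: impact score, Table-style counts, invariants, tf-idf."""

import pytest
from hypothesis import given, strategies as st

from ppimine import (
    EntityAnnotation,
    FEATURE_NAMES,
    FEATURE_SETS,
    ImpactConfig,
    SynthConfig,
    build_tfidf,
    build_triage_features,
    corpus_feature_vectors,
    features_to_frame,
    find_trigger_mentions,
    generate_synthetic_corpus,
    impact_score,
)

from .conftest import gene, make_doc


class TestImpactScore:
    def test_zero_without_cooccurrence(self):
        assert impact_score(0, 5, 3, 7) == 0.0
        assert impact_score(5, 0, 7, 3) == 0.0

    def test_upper_bound_at_document_maxima(self):
        assert impact_score(4, 9, 4, 9) == 1.0

    def test_half_mutation_full_interaction(self):
        assert impact_score(1, 1, 2, 1) == pytest.approx(0.75)

    def test_zero_maximum_with_positive_total_is_an_error(self):
        with pytest.raises(ValueError):
            impact_score(2, 3, 0, 5)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ImpactConfig(alpha=0.9, beta=0.9)

    @given(st.integers(1, 10), st.integers(1, 10), st.integers(0, 5))
    def test_monotone_in_mutation_total(self, mut, intl, bump):
        doc_max_mut, doc_max_int = mut + bump + 1, intl + 1
        lo = impact_score(mut, intl, doc_max_mut, doc_max_int)
        hi = impact_score(mut + bump, intl, doc_max_mut, doc_max_int)
        assert hi >= lo


class TestFeatureCounts:
    def test_repeated_interaction_term_counts_total_and_unique(self, term_lists):
        doc = make_doc("d", "Study.", "ProteinA interacts with an interaction partner.")
        matches = find_trigger_mentions(doc, term_lists)
        vec = build_triage_features(doc, [], [], matches, 0.5)
        assert vec["F1"] == 2
        assert vec["F2"] == 1

    def test_empty_document_is_all_zero(self):
        doc = make_doc("d", "Nothing here.", "Plain words only today.")
        vec = build_triage_features(doc, [], [], [], None)
        assert all(vec[n] == 0 for n in FEATURE_NAMES)

    def test_cross_sentence_triplet_counted_by_window_not_sentence(self, term_lists):
        doc = make_doc(
            "d",
            "Overview.",
            "A mutation was reported. AAA1 and BBB2 levels were strongly reduced.",
        )
        genes = [gene(doc, "AAA1", "101"), gene(doc, "BBB2", "102")]
        matches = find_trigger_mentions(doc, term_lists)
        vec = build_triage_features(doc, genes, [], matches, 0.5)
        assert vec["F15"] == 0
        assert vec["F26"] >= 1

    def test_term_cooccurrence_gates_sum_features(self, term_lists):
        only_int = make_doc("d", "T.", "The proteins interact in the assay.")
        vec = build_triage_features(
            only_int, [], [], find_trigger_mentions(only_int, term_lists), 0.0
        )
        assert vec["F1"] > 0 and vec["F3"] == 0
        assert vec["F5"] == 0 and vec["F6"] == 0

        both = make_doc("d", "T.", "The mutation altered how the proteins interact.")
        vec2 = build_triage_features(
            both, [], [], find_trigger_mentions(both, term_lists), 0.0
        )
        assert vec2["F5"] == vec2["F1"] + vec2["F3"]
        assert vec2["F6"] == vec2["F2"] + vec2["F4"]

    def test_tool_interaction_needs_two_distinct_gene_ids(self, term_lists):
        doc = make_doc("d", "T.", "AAA1 and AAA1 copies appeared. A mutation occurred there.")
        same = [gene(doc, "AAA1", "101", occurrence=0), gene(doc, "AAA1", "101", occurrence=1)]
        mut = EntityAnnotation(
            doc.doc_id, doc.text.index("mutation"), doc.text.index("mutation") + 8,
            "mutation", "Mutation", "", "pubtator",
        )
        vec = build_triage_features(doc, same, [mut], [], 0.0)
        assert vec["F17"] == 1  # one sentence with gene annotations
        assert vec["F18"] == 0  # but never two distinct ids
        assert vec["F12"] == 0

    def test_pie_score_copied_into_probability_feature(self):
        doc = make_doc("d", "T.", "Words.")
        assert build_triage_features(doc, [], [], [], 0.37)["F11"] == pytest.approx(0.37)

    def test_missing_pie_score_defaults_to_zero(self):
        doc = make_doc("d", "T.", "Words.")
        assert build_triage_features(doc, [], [], [], None)["F11"] == 0.0


class TestInvariantsOnSyntheticDraws:
    @given(st.integers(0, 2 ** 31 - 1))
    def test_all_invariants_hold_on_random_draws(self, seed):
        bundle = generate_synthetic_corpus(SynthConfig(n_docs=8, seed=seed))
        vectors, _ = corpus_feature_vectors(bundle)
        for vec in vectors:
            vec.validate()  # raises on violation
            assert vec["F19"] >= max(vec["F15"], vec["F18"])
            assert vec["F19"] <= vec["F15"] + vec["F18"]

    def test_feature_sets_cover_exactly_the_27_features(self):
        pooled = [f for group in FEATURE_SETS.values() for f in group]
        assert sorted(pooled) == sorted(FEATURE_NAMES)


class TestFrames:
    def test_frame_has_doc_index_and_feature_columns(self):
        bundle = generate_synthetic_corpus(SynthConfig(n_docs=5, seed=3))
        vectors, ids = corpus_feature_vectors(bundle)
        frame = features_to_frame(vectors, ids)
        assert list(frame.columns) == list(FEATURE_NAMES)
        assert list(frame.index) == ids

    def test_length_mismatch_is_an_error(self):
        bundle = generate_synthetic_corpus(SynthConfig(n_docs=5, seed=3))
        vectors, ids = corpus_feature_vectors(bundle)
        with pytest.raises(ValueError):
            features_to_frame(vectors, ids[:-1])


class TestTfidf:
    def test_identical_documents_have_identical_rows(self):
        texts = ["The kinase binds the receptor.", "The kinase binds the receptor."]
        X, _ = build_tfidf(texts)
        assert (X[0] != X[1]).nnz == 0

    def test_ubiquitous_token_has_minimal_idf(self):
        texts = [
            "kinase phosphorylation assay",
            "kinase receptor blot",
            "kinase unrelatedword sample",
        ]
        X, vec = build_tfidf(texts)
        idf = dict(zip(vec.get_feature_names_out(), vec.idf_))
        assert idf["kinas"] == min(idf.values())

    def test_unseen_token_contributes_nothing(self):
        X, vec = build_tfidf(["kinase receptor", "kinase assay"])
        row = vec.transform(["zzznovelword"])
        assert row.nnz == 0

    def test_stop_words_and_digits_dropped(self):
        _, vec = build_tfidf(["the of and 123 receptor"])
        vocab = set(vec.get_feature_names_out())
        assert "receptor" in vocab or "receptor" in {v for v in vocab}
        assert not vocab & {"the", "of", "and", "123"}

    def test_empty_vocabulary_is_an_error(self):
        with pytest.raises(ValueError):
            build_tfidf(["the of and"])
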