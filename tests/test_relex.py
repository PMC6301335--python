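"""Relation extraction: graphs, candidates, masking, features, end-to-end."""

import io

import pytest
from hypothesis import given, strategies as st

from ppimine import (
    CandidatePair,
    EntityAnnotation,
    RelationAnnotation,
    RelexModelConfig,
    SynthConfig,
    extract_relations_ml,
    filter_self_relations,
    generate_candidate_pairs,
    generate_synthetic_corpus,
    graph_features,
    join_graphs,
    label_candidates,
    mask_entities,
    micro_prf,
    train_relex,
)
from ppimine.relex import build_chain_graph, read_conllu, sentence_graphs

from .conftest import gene, make_doc


class TestGraphs:
    def test_chain_graph_links_consecutive_tokens(self):
        g = build_chain_graph("LAF1 binds HFR1")
        labels = [g.node_label(n) for n in sorted(g.graph.nodes)]
        assert labels == ["LAF1", "binds", "HFR1"]
        assert all(d["label"] == "next" for _, _, d in g.graph.edges(data=True))

    def test_join_conserves_nodes_and_adds_one_edge(self):
        g1 = build_chain_graph("A binds B")
        g2 = build_chain_graph("C binds D")
        joined = join_graphs(g1, g2)
        assert joined.graph.number_of_nodes() == (
            g1.graph.number_of_nodes() + g2.graph.number_of_nodes()
        )
        assert joined.graph.number_of_edges() == (
            g1.graph.number_of_edges() + g2.graph.number_of_edges() + 1
        )
        links = [
            d for _, _, d in joined.graph.edges(data=True) if d["label"] == "SENT_LINK"
        ]
        assert len(links) == 1

    def test_join_keeps_both_sentences_tokens(self):
        g1 = build_chain_graph("LAF1 interacts strongly")
        g2 = build_chain_graph("HFR1 is degraded")
        joined = join_graphs(g1, g2)
        labels = {joined.node_label(n) for n in joined.graph.nodes}
        assert {"LAF1", "HFR1"} <= labels

    def test_conllu_reader_builds_rooted_graph(self):
        doc = make_doc("d", "LAF1 binds HFR1.", "Nothing else.")
        conllu = (
            "1\tLAF1\t_\t_\t_\t_\t2\tnsubj\t_\t_\n"
            "2\tbinds\t_\t_\t_\t_\t0\troot\t_\t_\n"
            "3\tHFR1\t_\t_\t_\t_\t2\tobj\t_\t_\n"
            "\n"
            "1\tNothing\t_\t_\t_\t_\t2\tnsubj\t_\t_\n"
            "2\telse\t_\t_\t_\t_\t0\troot\t_\t_\n"
        )
        graphs = read_conllu(io.StringIO(conllu), doc)
        assert len(graphs) == 2
        root_label = graphs[0].node_label(graphs[0].root)
        assert root_label == "binds"


class TestCandidates:
    def test_single_sentence_pair(self):
        doc = make_doc("d", "Intro.", "LAF1 interacts with HFR1 strongly.")
        genes = [gene(doc, "LAF1", "1"), gene(doc, "HFR1", "2")]
        pairs = generate_candidate_pairs(doc, genes)
        assert len(pairs) == 1
        assert pairs[0].is_sentence_level

    def test_cross_sentence_pair_is_non_sentence_level(self):
        doc = make_doc("d", "Intro.", "LAF1 was expressed. HFR1 was silenced.")
        genes = [gene(doc, "LAF1", "1"), gene(doc, "HFR1", "2")]
        (pair,) = generate_candidate_pairs(doc, genes)
        assert not pair.is_sentence_level
        labels = {pair.graph.node_label(n) for n in pair.graph.graph.nodes}
        assert {"Protein1", "Protein2"} <= labels

    def test_triple_mention_enumeration_with_self_filter(self):
        doc = make_doc("d", "Intro.", "AAA1 binds AAA1 and BBB2 today.")
        genes = [
            gene(doc, "AAA1", "1", occurrence=0),
            gene(doc, "AAA1", "1", occurrence=1),
            gene(doc, "BBB2", "2"),
        ]
        pairs = generate_candidate_pairs(doc, genes)
        assert len(pairs) == 3  # (A,A), (A,B), (A,B)
        assert len(filter_self_relations(pairs)) == 2

    @given(st.integers(2, 6))
    def test_candidate_count_matches_pair_formula(self, m):
        words = " ".join(f"GN{i}X" for i in range(m)) + " cooperate."
        doc = make_doc("d", "Intro.", words)
        genes = [gene(doc, f"GN{i}X", str(i)) for i in range(m)]
        pairs = generate_candidate_pairs(doc, genes, max_sentence_distance=None)
        assert len(pairs) == m * (m - 1) // 2

    def test_distance_cap_drops_remote_pairs(self):
        sentences = "AAA1 starts here. Filler one. Filler two. Filler three. BBB2 ends here."
        doc = make_doc("d", "Intro.", sentences)
        genes = [gene(doc, "AAA1", "1"), gene(doc, "BBB2", "2")]
        assert generate_candidate_pairs(doc, genes, max_sentence_distance=3) == []
        assert len(generate_candidate_pairs(doc, genes, max_sentence_distance=None)) == 1


class TestMasking:
    def test_arguments_masked_in_document_order(self):
        doc = make_doc("d", "Intro.", "LAF1 interacts with HFR1.")
        genes = [gene(doc, "LAF1", "1"), gene(doc, "HFR1", "2")]
        (pair,) = generate_candidate_pairs(doc, genes)
        labels = [pair.graph.node_label(n) for n in sorted(pair.graph.graph.nodes)]
        assert labels[0] == "Protein1"
        assert "Protein2" in labels

    def test_bystander_entities_masked_by_type(self):
        doc = make_doc("d", "Intro.", "LAF1 with R97A binds HFR1 near CCC3.")
        genes = [gene(doc, "LAF1", "1"), gene(doc, "HFR1", "2")]
        bystanders = [
            gene(doc, "CCC3", "3"),
            EntityAnnotation(
                doc.doc_id, doc.text.index("R97A"), doc.text.index("R97A") + 4,
                "R97A", "Mutation", "", "pubtator",
            ),
        ]
        pairs = generate_candidate_pairs(
            doc, genes, all_annotations=genes + bystanders
        )
        pair = [p for p in pairs if p.id_pair == ("1", "2")][0]
        labels = {pair.graph.node_label(n) for n in pair.graph.graph.nodes}
        assert "Mutation_Other" in labels
        assert "Protein_Other" in labels

    def test_masking_preserves_topology(self):
        doc = make_doc("d", "Intro.", "LAF1 interacts with HFR1.")
        genes = [gene(doc, "LAF1", "1"), gene(doc, "HFR1", "2")]
        (pair,) = generate_candidate_pairs(doc, genes)
        base = build_chain_graph(doc.sentence_texts()[1], doc.sentences[1].start)
        assert set(pair.graph.graph.nodes) == set(base.graph.nodes)
        assert set(pair.graph.graph.edges) == set(base.graph.edges)


class TestSelfFilterAndLabels:
    def test_known_self_relation_removed(self):
        rels = [RelationAnnotation("d", ("673", "673"))]
        assert filter_self_relations(rels) == []

    def test_mixed_set_keeps_non_self(self):
        rels = [
            RelationAnnotation("d", ("1", "2")),
            RelationAnnotation("d", ("3", "3")),
            RelationAnnotation("d", ("4", "5")),
        ]
        assert len(filter_self_relations(rels)) == 2

    def test_gold_lookup_is_order_insensitive(self):
        doc = make_doc("d", "Intro.", "GA interacts with GB.")
        genes = [gene(doc, "GA", "5395"), gene(doc, "GB", "4292")]
        pairs = generate_candidate_pairs(doc, genes)
        gold = {RelationAnnotation("d", ("4292", "5395"))}
        labelled, counts = label_candidates(pairs, gold)
        assert labelled[0].label == 1
        assert counts[(True, 1)] == 1

    def test_absent_pair_labelled_negative(self):
        doc = make_doc("d", "Intro.", "GA interacts with GB.")
        genes = [gene(doc, "GA", "1"), gene(doc, "GB", "2")]
        labelled, _ = label_candidates(generate_candidate_pairs(doc, genes), set())
        assert labelled[0].label == 0


class TestGraphFeatures:
    def test_identical_graphs_identical_features(self):
        doc = make_doc("d", "Intro.", "LAF1 interacts with HFR1.")
        genes = [gene(doc, "LAF1", "1"), gene(doc, "HFR1", "2")]
        (p1,) = generate_candidate_pairs(doc, genes)
        (p2,) = generate_candidate_pairs(doc, genes)
        assert graph_features(p1.graph) == graph_features(p2.graph)

    def test_path_feature_on_three_node_chain(self):
        doc = make_doc("d", "GA binds GB", "")
        genes = [gene(doc, "GA", "1"), gene(doc, "GB", "2")]
        (pair,) = generate_candidate_pairs(doc, genes)
        feats = graph_features(pair.graph)
        path_keys = [k for k in feats if k.startswith("path:")]
        assert any(
            "protein1" in k and "binds" in k and "protein2" in k for k in path_keys
        )

    def test_missing_argument_node_is_an_error(self):
        g = build_chain_graph("no masked arguments here")
        with pytest.raises(ValueError):
            graph_features(g)


class TestEndToEnd:
    def test_planted_relations_recovered_on_held_out_documents(self):
        bundle = generate_synthetic_corpus(SynthConfig(n_docs=150, seed=7))
        genes_by_doc = {}
        for a in bundle.annotations:
            if a.entity_type == "Gene":
                genes_by_doc.setdefault(a.doc_id, []).append(a)
        candidates = []
        for doc in bundle.documents:
            candidates.extend(
                filter_self_relations(
                    generate_candidate_pairs(doc, genes_by_doc.get(doc.doc_id, []))
                )
            )
        labelled, _ = label_candidates(candidates, bundle.relations)
        # split by parity so both halves contain both document classes
        train_docs = {d.doc_id for i, d in enumerate(bundle.documents) if i % 2 == 0}
        test_docs = {d.doc_id for d in bundle.documents} - train_docs
        model = train_relex([c for c in labelled if c.doc_id in train_docs])
        predicted = extract_relations_ml(
            model, [c for c in candidates if c.doc_id in test_docs]
        )
        gold = {d: bundle.relations_for(d) for d in test_docs}
        for d in test_docs:
            predicted.setdefault(d, set())
        _, _, f1 = micro_prf(predicted, gold)
        assert f1 >= 0.9

    def test_output_invariant_to_candidate_order(self):
        bundle = generate_synthetic_corpus(SynthConfig(n_docs=30, seed=2))
        genes_by_doc = {}
        for a in bundle.annotations:
            if a.entity_type == "Gene":
                genes_by_doc.setdefault(a.doc_id, []).append(a)
        candidates = []
        for doc in bundle.documents:
            candidates.extend(
                filter_self_relations(
                    generate_candidate_pairs(doc, genes_by_doc.get(doc.doc_id, []))
                )
            )
        labelled, _ = label_candidates(candidates, bundle.relations)
        model = train_relex(labelled)
        fwd = extract_relations_ml(model, labelled)
        rev = extract_relations_ml(model, list(reversed(labelled)))
        assert fwd == rev
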