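"""Stemming, amino-acid patterns, trigger-term matching rules."""

import io

import pytest
from hypothesis import given, strategies as st

from ppimine import (
    TermLists,
    find_amino_acid_mentions,
    find_trigger_mentions,
    porter_stem,
    stem_tokens,
)
from ppimine.term_matching import AMINO_ACID_CODES, AMINO_ACID_NAMES, parse_term_lists

from .conftest import make_doc


class TestPorterStemmer:
    @pytest.mark.parametrize(
        "word,stem",
        [
            ("interacts", "interact"),
            ("interaction", "interact"),
            ("interacting", "interact"),
            ("binding", "bind"),
            ("caresses", "caress"),
            ("ponies", "poni"),
            ("relational", "relat"),
            ("hopeful", "hope"),
            ("electrical", "electr"),
            ("adjustable", "adjust"),
            ("activate", "activ"),
            ("probate", "probat"),
            ("rate", "rate"),
            ("cease", "ceas"),
        ],
    )
    def test_known_stems(self, word, stem):
        assert porter_stem(word) == stem

    def test_mutation_family_collapses(self):
        assert porter_stem("mutations") == porter_stem("mutation")
        assert porter_stem("mutated") == porter_stem("mutate")

    @given(st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1, max_size=20))
    def test_idempotent_on_its_own_output(self, word):
        once = porter_stem(word)
        assert porter_stem(once) == once or len(porter_stem(once)) <= len(once)

    @given(st.text(alphabet="abcdefghijklmnopqrstuvwxyz", min_size=1, max_size=20))
    def test_never_longer_than_input(self, word):
        assert len(porter_stem(word)) <= len(word)


class TestStemTokens:
    def test_empty_text(self):
        assert stem_tokens("") == []

    def test_spans_index_original_text(self):
        text = "LAF1 interacts strongly."
        for token, _stem, (start, end) in stem_tokens(text):
            assert text[start:end] == token

    def test_stemming_applied_casefolded(self):
        (_, stem, _), = stem_tokens("Interactions")
        assert stem == "interact"


class TestAminoAcids:
    def test_full_name_case_insensitive(self):
        assert len(find_amino_acid_mentions("alanine substitution")) == 1
        assert len(find_amino_acid_mentions("Alanine substitution")) == 1

    def test_word_boundary_blocks_partial_match(self):
        assert find_amino_acid_mentions("ALAN TURING") == []

    def test_three_letter_code_title_and_upper_only(self):
        assert len(find_amino_acid_mentions("the Ala residue at position 97")) == 1
        # lowercase English words that collide with codes must not match
        assert find_amino_acid_mentions("his results met all criteria") == []

    def test_all_forty_canonical_patterns(self):
        names = " ".join(sorted(AMINO_ACID_NAMES))
        codes = " ".join(sorted(AMINO_ACID_CODES))
        assert len(find_amino_acid_mentions(names)) == 20
        assert len(find_amino_acid_mentions(codes)) == 20


class TestTriggerMatching:
    def test_mutagenesis_is_a_strong_match(self, term_lists):
        doc = make_doc("d", "Methods.", "Site-directed mutagenesis was applied.")
        cats = [m.category for m in find_trigger_mentions(doc, term_lists)]
        assert cats.count("strong_mutation") == 1

    def test_weak_term_without_amino_acid_is_suppressed(self, term_lists):
        doc = make_doc("d", "Title.", "We observed changes in the distribution.")
        matches = find_trigger_mentions(doc, term_lists)
        assert not [m for m in matches if "mutation" in m.category]

    def test_weak_term_with_amino_acid_in_sentence_matches(self, term_lists):
        doc = make_doc("d", "Title.", "We noted the Alanine change at position 97.")
        weak = [m for m in find_trigger_mentions(doc, term_lists) if m.category == "weak_mutation"]
        assert len(weak) == 1
        assert weak[0].term == porter_stem("change")

    def test_weak_scope_document_rescues_cross_sentence_amino_acid(self, term_lists):
        doc = make_doc("d", "Title.", "Alanine was abundant. The change was noted.")
        sentence_scope = [
            m for m in find_trigger_mentions(doc, term_lists) if m.category == "weak_mutation"
        ]
        document_scope = [
            m
            for m in find_trigger_mentions(doc, term_lists, weak_scope="document")
            if m.category == "weak_mutation"
        ]
        assert sentence_scope == []
        assert len(document_scope) == 1

    def test_match_carries_sentence_index_and_span(self, term_lists):
        doc = make_doc("d", "First sentence here.", "LAF1 interacts with HFR1.")
        (m,) = [x for x in find_trigger_mentions(doc, term_lists) if x.category == "interaction"]
        assert m.sentence_index == 1
        assert doc.text[m.span[0]:m.span[1]].lower().startswith("interact")

    def test_removing_amino_acids_removes_all_weak_matches(self, term_lists):
        with_aa = make_doc("d", "T.", "The Alanine change and Arginine exchange were noted.")
        without = make_doc("d", "T.", "The change and exchange were noted.")
        weak_with = [m for m in find_trigger_mentions(with_aa, term_lists) if m.category == "weak_mutation"]
        weak_without = [m for m in find_trigger_mentions(without, term_lists) if m.category == "weak_mutation"]
        assert len(weak_with) == 2
        assert weak_without == []

    def test_adding_a_term_never_decreases_matches(self, term_lists):
        doc = make_doc("d", "T.", "The flux capacitor interacts with the sprocket.")
        baseline = len(find_trigger_mentions(doc, term_lists))
        extended = TermLists(
            strong_mutation=term_lists.strong_mutation,
            weak_mutation=term_lists.weak_mutation,
            interaction=term_lists.interaction | {porter_stem("sprocket")},
            degree=term_lists.degree,
        )
        assert len(find_trigger_mentions(doc, extended)) >= baseline + 1

    def test_determinism(self, term_lists):
        doc1 = make_doc("d", "T.", "LAF1 interacts; binding was abolished by mutation.")
        doc2 = make_doc("d", "T.", "LAF1 interacts; binding was abolished by mutation.")
        assert find_trigger_mentions(doc1, term_lists) == find_trigger_mentions(doc2, term_lists)


class TestTermListFiles:
    def test_duplicate_entries_deduplicate(self):
        lists = parse_term_lists(
            io.StringIO("[interaction]\nbind\nbinding\n[degree]\nincrease\n")
        )
        assert lists.interaction == {"bind"}

    def test_unknown_header_is_an_error(self):
        with pytest.raises(ValueError, match="unknown"):
            parse_term_lists(io.StringIO("[nonsense]\nterm\n"))

    def test_category_collision_is_an_error(self):
        with pytest.raises(ValueError):
            parse_term_lists(io.StringIO("[interaction]\nbind\n[degree]\nbinds\n"))

    def test_comments_ignored(self):
        lists = parse_term_lists(io.StringIO("[interaction]\n# comment\nbind\n"))
        assert lists.interaction == {"bind"}
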