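"""Trigger-term detection for mutations, interactions and degree words.

Terms are curated in four categories.  ``strong_mutation`` terms signal a
mutation unconditionally ("mutagenesis", "substitution"); ``weak_mutation``
terms ("change", "damage") signal one only when an amino acid is co-mentioned
in scope, since they are common in unrelated contexts ("changes in the
distribution").  ``interaction`` terms name physical interactions ("interact",
"bind", "complex"); ``degree`` terms describe how a mutation modulates an
interaction ("abolish", "enhance", "reduce").

Matching is performed on Porter stems of the document tokens against stemmed
list entries, so surface inflections ("interacts", "interacting") hit the
same entry.  Symbolic zygosity terms ("-/-", "+/-") are matched literally
before tokenization.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from .corpus_io import Document

logger = logging.getLogger(__name__)

CATEGORIES = ("strong_mutation", "weak_mutation", "interaction", "degree")


# ---------------------------------------------------------------------------
# Porter stemmer
# ---------------------------------------------------------------------------

_VOWELS = "aeiou"


def _is_consonant(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_consonant(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in the stem (the Porter *m* measure)."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        vowel = not _is_consonant(stem, i)
        if prev_vowel and not vowel:
            m += 1
        prev_vowel = vowel
    return m


def _contains_vowel(stem: str) -> bool:
    return any(not _is_consonant(stem, i) for i in range(len(stem)))


def _ends_double_consonant(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_consonant(word, len(word) - 1)
    )


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (
        _is_consonant(word, len(word) - 3)
        and not _is_consonant(word, len(word) - 2)
        and _is_consonant(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement", "ment",
    "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    """Classic Porter stemming of a single lower-cased word."""
    word = word.lower()
    if len(word) <= 2 or not word.isalpha():
        return word

    # step 1a
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith("ies"):
        word = word[:-2]
    elif word.endswith("ss"):
        pass
    elif word.endswith("s"):
        word = word[:-1]

    # step 1b
    if word.endswith("eed"):
        if _measure(word[:-3]) > 0:
            word = word[:-1]
    else:
        flag = False
        if word.endswith("ed") and _contains_vowel(word[:-2]):
            word, flag = word[:-2], True
        elif word.endswith("ing") and _contains_vowel(word[:-3]):
            word, flag = word[:-3], True
        if flag:
            if word.endswith(("at", "bl", "iz")):
                word += "e"
            elif _ends_double_consonant(word) and word[-1] not in "lsz":
                word = word[:-1]
            elif _measure(word) == 1 and _ends_cvc(word):
                word += "e"

    # step 1c
    if word.endswith("y") and _contains_vowel(word[:-1]):
        word = word[:-1] + "i"

    # step 2
    for suffix, repl in _STEP2:
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if _measure(stem) > 0:
                word = stem + repl
            break

    # step 3
    for suffix, repl in _STEP3:
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if _measure(stem) > 0:
                word = stem + repl
            break

    # step 4
    for suffix in _STEP4:
        if word.endswith(suffix):
            stem = word[: -len(suffix)]
            if _measure(stem) > 1:
                if suffix == "ion" and (not stem or stem[-1] not in "st"):
                    continue
                word = stem
            break

    # step 5a
    if word.endswith("e"):
        stem = word[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            word = stem

    # step 5b
    if _measure(word) > 1 and _ends_double_consonant(word) and word.endswith("l"):
        word = word[:-1]

    return word


# ---------------------------------------------------------------------------
# tokenization
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def stem_tokens(text: str) -> list[tuple[str, str, tuple[int, int]]]:
    """Tokenize and stem, keeping original-character spans.

    Returns ``(token, stem, (start, end))`` triples.  Stop words are retained;
    their removal is a tf-idf concern only.
    """
    return [
        (m.group(0), porter_stem(m.group(0)), (m.start(), m.end()))
        for m in _TOKEN_RE.finditer(text)
    ]


# ---------------------------------------------------------------------------
# amino-acid mentions
# ---------------------------------------------------------------------------

AMINO_ACID_NAMES = (
    "alanine", "arginine", "asparagine", "aspartate", "cysteine", "glutamine",
    "glutamate", "glycine", "histidine", "isoleucine", "leucine", "lysine",
    "methionine", "phenylalanine", "proline", "serine", "threonine",
    "tryptophan", "tyrosine", "valine",
)

AMINO_ACID_CODES = (
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
)

_NAMES_RE = re.compile(
    r"\b(?:" + "|".join(AMINO_ACID_NAMES) + r")\b", re.IGNORECASE
)
# Codes are matched case-sensitively in Title or UPPER case; lower-case
# matching would hit common English words ("his", "met", "pro").
_CODES_RE = re.compile(
    r"\b(?:" + "|".join(c + "|" + c.upper() for c in AMINO_ACID_CODES) + r")\b"
)


def find_amino_acid_mentions(text: str) -> list[tuple[int, int]]:
    """Spans of amino-acid full names and standard 3-letter codes."""
    spans = {(m.start(), m.end()) for m in _NAMES_RE.finditer(text)}
    for m in _CODES_RE.finditer(text):
        # skip codes that are a prefix of a full-name match
        if not any(s <= m.start() < e for s, e in spans):
            spans.add((m.start(), m.end()))
    return sorted(spans)


# ---------------------------------------------------------------------------
# term lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermLists:
    """Stemmed, lower-cased trigger terms in four disjoint categories.

    Multi-word entries are stored as space-joined stem sequences; symbolic
    entries (containing ``/``) are kept verbatim.
    """

    strong_mutation: frozenset[str]
    weak_mutation: frozenset[str]
    interaction: frozenset[str]
    degree: frozenset[str]

    def __post_init__(self) -> None:
        cats = [getattr(self, c) for c in CATEGORIES]
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                clash = cats[i] & cats[j]
                if clash:
                    raise ValueError(
                        f"term categories {CATEGORIES[i]} and {CATEGORIES[j]} "
                        f"share stems: {sorted(clash)}"
                    )

    def category_of(self, stem: str) -> str | None:
        for cat in CATEGORIES:
            if stem in getattr(self, cat):
                return cat
        return None


def _stem_entry(entry: str) -> str:
    if "/" in entry:  # symbolic terms like -/- and +/-
        return entry
    return " ".join(porter_stem(tok) for tok in entry.lower().split())


def parse_term_lists(lines: Iterable[str]) -> TermLists:
    sections: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    current: str | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip() if not raw.strip().startswith("#") else ""
        if raw.strip().startswith("#") or not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1]
            if name not in sections:
                raise ValueError(f"line {lineno}: unknown section header {line!r}")
            current = name
            continue
        if current is None:
            raise ValueError(f"line {lineno}: term {line!r} outside any section")
        sections[current].add(_stem_entry(line))
    for cat, terms in sections.items():
        if not terms:
            logger.warning("term-list category %s is empty", cat)
        else:
            logger.info("term-list category %s: %d stemmed entries", cat, len(terms))
    return TermLists(**{c: frozenset(sections[c]) for c in CATEGORIES})


def load_term_lists(path: str | Path | None = None) -> TermLists:
    """Load term lists from ``path``, or the packaged default lists."""
    if path is None:
        text = (
            resources.files("ppimine").joinpath("data/term_lists.txt").read_text()
        )
        return parse_term_lists(text.splitlines())
    return parse_term_lists(Path(path).read_text().splitlines())


# ---------------------------------------------------------------------------
# trigger matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TermMatch:
    doc_id: str
    sentence_index: int
    span: tuple[int, int]
    term: str
    category: str


def find_trigger_mentions(
    doc: Document,
    lists: TermLists,
    weak_scope: str = "sentence",
) -> list[TermMatch]:
    """All trigger-term matches in a sentence-segmented document.

    Strong-mutation, interaction and degree matches are emitted
    unconditionally.  Weak-mutation matches are emitted only when an amino
    acid is co-mentioned within ``weak_scope`` ("sentence" or "document").
    """
    if weak_scope not in ("sentence", "document"):
        raise ValueError(f"weak_scope must be 'sentence' or 'document', got {weak_scope!r}")
    if all(not getattr(lists, c) for c in CATEGORIES):
        logger.warning("all term-list categories are empty; no matches possible")
        return []
    if not doc.sentences:
        doc.segment()

    text = doc.text
    doc_has_aa = bool(find_amino_acid_mentions(text)) if weak_scope == "document" else False

    multiword = {
        cat: sorted(
            (t.split() for t in getattr(lists, cat) if " " in t),
            key=len,
            reverse=True,
        )
        for cat in CATEGORIES
    }
    symbolic = {
        cat: [t for t in getattr(lists, cat) if "/" in t] for cat in CATEGORIES
    }

    matches: list[TermMatch] = []
    for s_idx, span in enumerate(doc.sentences):
        sent = text[span.start:span.end]
        tokens = stem_tokens(sent)
        sent_has_aa = (
            doc_has_aa
            if weak_scope == "document"
            else bool(find_amino_acid_mentions(sent))
        )
        covered: set[int] = set()

        def emit(cat: str, term: str, start: int, end: int) -> None:
            if cat == "weak_mutation" and not sent_has_aa:
                return
            matches.append(
                TermMatch(doc.doc_id, s_idx, (span.start + start, span.start + end), term, cat)
            )

        # symbolic literals first
        for cat in CATEGORIES:
            for sym in symbolic[cat]:
                pos = sent.find(sym)
                while pos != -1:
                    emit(cat, sym, pos, pos + len(sym))
                    pos = sent.find(sym, pos + len(sym))

        # multi-word stem sequences, longest first
        for cat in CATEGORIES:
            for seq in multiword[cat]:
                L = len(seq)
                for i in range(len(tokens) - L + 1):
                    if any(j in covered for j in range(i, i + L)):
                        continue
                    if [tokens[j][1] for j in range(i, i + L)] == seq:
                        emit(cat, " ".join(seq), tokens[i][2][0], tokens[i + L - 1][2][1])
                        covered.update(range(i, i + L))

        # single stems
        for i, (_tok, stem, (t_start, t_end)) in enumerate(tokens):
            if i in covered:
                continue
            cat = lists.category_of(stem)
            if cat is not None:
                emit(cat, stem, t_start, t_end)

    matches.sort(key=lambda m: (m.sentence_index, m.span))
    return matches
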