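"""Reading and writing PubTator-dialect corpora.

The corpus dialect is the plain-text standoff format used to distribute
abstract collections for PPIm curation:

* ``pmid|t|title`` and ``pmid|a|abstract`` text lines;
* annotation lines ``pmid<TAB>start<TAB>end<TAB>surface<TAB>type<TAB>normid``
  (an optional seventh column names the annotation source);
* relation lines ``pmid<TAB>PPIm<TAB>id1<TAB>id2`` (the ``PPIm`` column may be
  omitted);
* documents separated by blank lines.

Character offsets are 0-based half-open over ``title + " " + abstract``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, NamedTuple

logger = logging.getLogger(__name__)

ENTITY_TYPES = frozenset({"Gene", "Mutation", "Species", "Chemical", "Other"})
SOURCES = frozenset({"task", "gnorm", "pubtator", "synthetic"})

#: abbreviation tokens (lowercase, without the trailing period) after which a
#: sentence boundary is suppressed
ABBREVIATIONS = frozenset(
    {
        "e.g", "i.e", "cf", "vs", "al", "et al", "fig", "figs", "ref", "refs",
        "no", "ca", "approx", "dr", "p", "c", "g", "m",
    }
)


class SentenceSpan(NamedTuple):
    """Half-open character span of one sentence over a document's text."""

    start: int
    end: int


@dataclass
class Document:
    doc_id: str
    title: str
    abstract: str
    sentences: list[SentenceSpan] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    @property
    def text(self) -> str:
        return self.title + " " + self.abstract if self.abstract else self.title

    def segment(self) -> "Document":
        """Populate sentence spans in place and return self."""
        self.sentences = split_sentences(self.text)
        return self

    def sentence_texts(self) -> list[str]:
        return [self.text[s.start:s.end] for s in self.sentences]

    def sentence_index_of(self, offset: int) -> int:
        """Index of the sentence whose span contains ``offset``; -1 if none."""
        for i, span in enumerate(self.sentences):
            if span.start <= offset < span.end:
                return i
        return -1


@dataclass(frozen=True, order=True)
class EntityAnnotation:
    doc_id: str
    start: int
    end: int
    surface: str
    entity_type: str
    norm_id: str = ""
    source: str = "task"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span ({self.start}, {self.end})")
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.entity_type!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True, order=True)
class RelationAnnotation:
    """A document-level relation between two normalized gene ids.

    The pair is unordered and stored lexicographically sorted, so duplicates
    with swapped arguments collapse.
    """

    doc_id: str
    pair: tuple[str, str]

    def __post_init__(self) -> None:
        a, b = self.pair
        if not a or not b:
            raise ValueError("relation ids must be non-empty")
        if a > b:
            object.__setattr__(self, "pair", (b, a))


def canonical_pair(id_a: str, id_b: str) -> tuple[str, str]:
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


@dataclass
class CorpusBundle:
    documents: list[Document] = field(default_factory=list)
    annotations: set[EntityAnnotation] = field(default_factory=set)
    relations: set[RelationAnnotation] = field(default_factory=set)
    labels: dict[str, int] = field(default_factory=dict)
    scores: dict[str, float] = field(default_factory=dict)

    def doc_index(self) -> dict[str, Document]:
        return {d.doc_id: d for d in self.documents}

    def annotations_for(self, doc_id: str) -> list[EntityAnnotation]:
        return sorted(a for a in self.annotations if a.doc_id == doc_id)

    def relations_for(self, doc_id: str) -> set[RelationAnnotation]:
        return {r for r in self.relations if r.doc_id == doc_id}

    def validate(self) -> None:
        docs = self.doc_index()
        for ann in self.annotations:
            if ann.doc_id not in docs:
                raise ValueError(f"annotation references unknown doc {ann.doc_id!r}")
            text = docs[ann.doc_id].text
            if ann.end > len(text):
                raise ValueError(
                    f"doc {ann.doc_id}: span ({ann.start}, {ann.end}) outside text "
                    f"of length {len(text)}"
                )
            found = text[ann.start:ann.end]
            if found != ann.surface:
                raise ValueError(
                    f"doc {ann.doc_id}: surface mismatch at ({ann.start}, {ann.end}): "
                    f"expected {ann.surface!r}, found {found!r}"
                )
        for rel in self.relations:
            if rel.doc_id not in docs:
                raise ValueError(f"relation references unknown doc {rel.doc_id!r}")
        for mapping_name, mapping in (("label", self.labels), ("score", self.scores)):
            for doc_id in mapping:
                if doc_id not in docs:
                    raise ValueError(f"{mapping_name} references unknown doc {doc_id!r}")


# ---------------------------------------------------------------------------
# sentence segmentation
# ---------------------------------------------------------------------------

def split_sentences(text: str) -> list[SentenceSpan]:
    """Rule-based sentence segmentation.

    Splits after ``.?!`` runs that are followed by whitespace and an upper-case
    letter or digit, with an abbreviation guard (``e.g.``, ``Fig.``, mutation
    nomenclature prefixes such as ``p.``) so that tokens like ``p.R97A`` are
    never split.  Spans are trimmed to non-whitespace.
    """
    if not text or text.isspace():
        return []
    boundaries: list[int] = []
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch in ".?!":
            j = i
            while j + 1 < n and text[j + 1] in ".?!":
                j += 1
            k = j + 1
            if k < n and text[k].isspace():
                m = k
                while m < n and text[m].isspace():
                    m += 1
                if m < n and (text[m].isupper() or text[m].isdigit()):
                    if ch != "." or not _is_abbreviation(text, i):
                        boundaries.append(k)
            i = j + 1
        else:
            i += 1
    spans: list[SentenceSpan] = []
    prev = 0
    for b in boundaries + [n]:
        seg = text[prev:b]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        if seg.strip():
            spans.append(SentenceSpan(prev + lead, b - trail))
        prev = b
    return spans


def _is_abbreviation(text: str, period_index: int) -> bool:
    start = period_index
    while start > 0 and not text[start - 1].isspace():
        start -= 1
    token = text[start:period_index].lower().rstrip(".")
    if not token:
        return True
    if token in ABBREVIATIONS:
        return True
    # two-token abbreviations ("et al.")
    if start > 0:
        prev_start = start - 1
        while prev_start > 0 and not text[prev_start - 1].isspace():
            prev_start -= 1
        two = (text[prev_start:period_index].lower().rstrip("."))
        if two in ABBREVIATIONS:
            return True
    return False


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_pubtator_corpus(stream: IO[str] | Iterable[str], source: str = "task") -> CorpusBundle:
    """Parse a PubTator-dialect stream into a validated :class:`CorpusBundle`.

    ``source`` tags annotation lines that carry no explicit seventh column.
    Malformed lines raise :class:`ValueError` naming the line number.
    """
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    order: list[str] = []
    raw_annotations: list[tuple[int, tuple]] = []
    relations: set[RelationAnnotation] = set()

    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        if "|" in line and "\t" not in line:
            parts = line.split("|", 2)
            if len(parts) != 3 or parts[1] not in ("t", "a"):
                raise ValueError(f"line {lineno}: malformed text line {line!r}")
            doc_id, kind, content = parts
            if doc_id not in titles and doc_id not in abstracts:
                order.append(doc_id)
            if kind == "t":
                titles[doc_id] = content
            else:
                abstracts[doc_id] = content
            continue
        fields = line.split("\t")
        if len(fields) in (3, 4) and _looks_like_relation(fields):
            doc_id = fields[0]
            ids = fields[1:] if len(fields) == 3 else fields[2:]
            relations.add(RelationAnnotation(doc_id, canonical_pair(ids[0], ids[1])))
        elif len(fields) in (5, 6, 7):
            doc_id, start_s, end_s, surface, etype = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-integer offsets in {line!r}") from exc
            norm_id = fields[5] if len(fields) >= 6 else ""
            ann_source = fields[6] if len(fields) == 7 else source
            if norm_id in ("-", "None"):
                norm_id = ""
            raw_annotations.append(
                (lineno, (doc_id, start, end, surface, etype, norm_id, ann_source))
            )
        else:
            raise ValueError(f"line {lineno}: unrecognized line {line!r}")

    documents = [
        Document(doc_id, titles.get(doc_id, ""), abstracts.get(doc_id, "")).segment()
        for doc_id in order
    ]
    bundle = CorpusBundle(documents=documents, relations=relations)
    docs = bundle.doc_index()
    for lineno, (doc_id, start, end, surface, etype, norm_id, ann_source) in raw_annotations:
        if doc_id not in docs:
            raise ValueError(f"line {lineno}: annotation for unknown doc {doc_id!r}")
        text = docs[doc_id].text
        if not (0 <= start < end <= len(text)):
            raise ValueError(
                f"line {lineno}: doc {doc_id}: span ({start}, {end}) outside text "
                f"of length {len(text)}"
            )
        found = text[start:end]
        if found != surface:
            raise ValueError(
                f"line {lineno}: doc {doc_id}: surface mismatch: expected "
                f"{surface!r}, found {found!r}"
            )
        bundle.annotations.add(
            EntityAnnotation(doc_id, start, end, surface, etype, norm_id, ann_source)
        )
    for rel in relations:
        if rel.doc_id not in docs:
            raise ValueError(f"relation line references unknown doc {rel.doc_id!r}")
    return bundle


def _looks_like_relation(fields: list[str]) -> bool:
    if len(fields) == 4:
        return fields[1].upper() in ("PPIM", "PPI", "RELATION")
    # three fields: doc, id1, id2 -- ids are not offsets
    try:
        int(fields[1])
        int(fields[2])
    except ValueError:
        return False
    # ambiguity with truncated annotation lines is resolved by field count
    return True


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_pubtator_corpus(bundle: CorpusBundle, stream: IO[str]) -> None:
    """Serialize a bundle; annotations are emitted sorted for stable output.

    ``read_pubtator_corpus(write_pubtator_corpus(b))`` reproduces ``b``.
    """
    for doc in bundle.documents:
        stream.write(f"{doc.doc_id}|t|{doc.title}\n")
        stream.write(f"{doc.doc_id}|a|{doc.abstract}\n")
        for ann in sorted(bundle.annotations_for(doc.doc_id)):
            stream.write(
                f"{ann.doc_id}\t{ann.start}\t{ann.end}\t{ann.surface}\t"
                f"{ann.entity_type}\t{ann.norm_id}\t{ann.source}\n"
            )
        for rel in sorted(bundle.relations_for(doc.doc_id)):
            stream.write(f"{rel.doc_id}\tPPIm\t{rel.pair[0]}\t{rel.pair[1]}\n")
        stream.write("\n")


def read_labels(stream: IO[str] | Iterable[str]) -> dict[str, int]:
    """Read a ``pmid<TAB>0|1`` label file."""
    labels: dict[str, int] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        doc_id, _, value = line.partition("\t")
        if value not in ("0", "1"):
            raise ValueError(f"line {lineno}: label must be 0 or 1, got {value!r}")
        labels[doc_id] = int(value)
    return labels


def read_scores(stream: IO[str] | Iterable[str]) -> dict[str, float]:
    """Read a ``pmid<TAB>float`` interaction-probability score file."""
    scores: dict[str, float] = {}
    for lineno, line in enumerate(stream, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        doc_id, _, value = line.partition("\t")
        score = float(value)
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"line {lineno}: score {score} outside [0, 1]")
        scores[doc_id] = score
    return scores


def write_labels(labels: dict[str, int], stream: IO[str]) -> None:
    for doc_id in sorted(labels):
        stream.write(f"{doc_id}\t{labels[doc_id]}\n")


def write_scores(scores: dict[str, float], stream: IO[str]) -> None:
    for doc_id in sorted(scores):
        stream.write(f"{doc_id}\t{scores[doc_id]:.6f}\n")


def load_term_lists(path):
    """Load a sectioned term-list file; see :mod:`ppimine.term_matching`."""
    from .term_matching import load_term_lists as _load

    return _load(path)
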