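"""Heuristic PPIm extraction by sentence-level co-occurrence counting.

Three rules filter the pool of gene pairs that co-occur within a sentence:

* H1 — drop self-relations (a protein is assumed not to interact with itself);
* H2 — keep a pair when it co-occurs in at least ``N`` sentences of the
  abstract (default ``N = 3``);
* H3 (default rule) — additionally keep a below-threshold pair when it is the
  only pair mentioned in some sentence that also contains the trigger word
  "interact" (matched on stems, so "interacts"/"interaction" qualify).

Mentions without a normalized gene id are ignored; only genes with ids can be
reported as document-level pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .corpus_io import Document, EntityAnnotation, RelationAnnotation, canonical_pair
from .evaluation import micro_prf
from .term_matching import porter_stem, stem_tokens


@dataclass(frozen=True)
class CoocConfig:
    N: int = 3
    trigger: str = "interact"
    default_rule_enabled: bool = True
    stem_trigger: bool = True

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("sentence-count threshold N must be >= 1")


def pair_sentence_counts(
    doc: Document, gene_annotations: Iterable[EntityAnnotation]
) -> tuple[dict[tuple[str, str], int], list[set[str]]]:
    """Per-pair count of sentences containing both ids, plus per-sentence ids."""
    if not doc.sentences:
        doc.segment()
    ids_per_sentence: list[set[str]] = [set() for _ in doc.sentences]
    for ann in gene_annotations:
        if ann.doc_id != doc.doc_id or not ann.norm_id:
            continue
        idx = doc.sentence_index_of(ann.start)
        if idx >= 0:
            ids_per_sentence[idx].add(ann.norm_id)
    counts: dict[tuple[str, str], int] = {}
    for ids in ids_per_sentence:
        for a, b in itertools.combinations(sorted(ids), 2):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    return counts, ids_per_sentence


def extract_relations_cooccurrence(
    doc: Document,
    gene_annotations: Iterable[EntityAnnotation],
    cfg: CoocConfig = CoocConfig(),
) -> set[RelationAnnotation]:
    """Apply H1–H3 to one document and return its extracted id pairs."""
    counts, ids_per_sentence = pair_sentence_counts(doc, gene_annotations)
    # H1 is implicit: itertools.combinations over distinct sorted ids never
    # produces a self pair.
    result = {
        RelationAnnotation(doc.doc_id, pair)
        for pair, count in counts.items()
        if count >= cfg.N
    }
    if cfg.default_rule_enabled:
        trigger = porter_stem(cfg.trigger) if cfg.stem_trigger else cfg.trigger
        for idx, ids in enumerate(ids_per_sentence):
            pairs = list(itertools.combinations(sorted(ids), 2))
            if len(pairs) != 1:
                continue
            span = doc.sentences[idx]
            sentence = doc.text[span.start:span.end]
            if cfg.stem_trigger:
                present = any(stem == trigger for _t, stem, _s in stem_tokens(sentence))
            else:
                present = trigger in sentence
            if present:
                result.add(RelationAnnotation(doc.doc_id, pairs[0]))
    return result


def extract_corpus_cooccurrence(
    documents: Iterable[Document],
    annotations: Iterable[EntityAnnotation],
    cfg: CoocConfig = CoocConfig(),
) -> dict[str, set[RelationAnnotation]]:
    by_doc: dict[str, list[EntityAnnotation]] = {}
    for ann in annotations:
        if ann.entity_type == "Gene":
            by_doc.setdefault(ann.doc_id, []).append(ann)
    return {
        doc.doc_id: extract_relations_cooccurrence(doc, by_doc.get(doc.doc_id, []), cfg)
        for doc in documents
    }


def threshold_sweep(
    documents: list[Document],
    annotations: Iterable[EntityAnnotation],
    gold: Mapping[str, Iterable[RelationAnnotation]],
    n_range: Iterable[int],
    cfg: CoocConfig = CoocConfig(),
) -> pd.DataFrame:
    """Micro P/R/F of the extractor for each sentence-count threshold N."""
    n_values = list(n_range)
    if not n_values:
        raise ValueError("empty threshold range")
    annotations = list(annotations)
    rows = []
    for n in n_values:
        predicted = extract_corpus_cooccurrence(
            documents,
            annotations,
            CoocConfig(n, cfg.trigger, cfg.default_rule_enabled, cfg.stem_trigger),
        )
        p, r, f = micro_prf(predicted, gold)
        rows.append({"N": n, "precision": p, "recall": r, "f1": f})
    return pd.DataFrame(rows)
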