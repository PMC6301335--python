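"""Merging gene annotations from multiple annotators.

Different entity annotators disagree both on spans (one tool may annotate a
coordinated phrase such as "myosin-binding protein C, and desmin" while
another annotates only "desmin") and on normalized ids (a shared gene symbol
can map to different organisms).  The ensemble resolves overlapping gene
annotations by taking the minimal superstring span and the id from the
highest-priority source; non-gene annotations pass through untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus_io import EntityAnnotation, RelationAnnotation

logger = logging.getLogger(__name__)

DEFAULT_PRIORITY = ("task", "gnorm", "pubtator")


@dataclass(frozen=True)
class PriorityOrder:
    """Source precedence for id conflicts; unlisted sources rank last."""

    order: tuple[str, ...] = DEFAULT_PRIORITY

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise ValueError("priority order contains duplicate sources")

    def rank(self, source: str) -> int:
        try:
            return self.order.index(source)
        except ValueError:
            return len(self.order)


def spans_overlap(a: EntityAnnotation, b: EntityAnnotation) -> bool:
    """True iff the two annotations share at least one character (half-open)."""
    if a.doc_id != b.doc_id:
        raise ValueError(f"annotations from different documents: {a.doc_id} vs {b.doc_id}")
    return max(a.start, b.start) < min(a.end, b.end)


def _stitch_surface(a: EntityAnnotation, b: EntityAnnotation) -> str:
    """Surface of the minimal superstring, built from two overlapping spans."""
    first, second = (a, b) if (a.start, a.end) <= (b.start, b.end) else (b, a)
    if second.end <= first.end:
        return first.surface
    return first.surface + second.surface[first.end - second.start:]


def merge_overlapping(
    a: EntityAnnotation,
    b: EntityAnnotation,
    priority: PriorityOrder = PriorityOrder(),
) -> EntityAnnotation:
    """Merge two overlapping gene annotations into one.

    The span is the minimal superstring of both spans.  The norm id and source
    come from the higher-priority source; between equal-priority sources the
    longer span's id wins, with ties broken toward the lexicographically
    smaller id.  Annotations lacking a norm id never supply the id.
    """
    if not spans_overlap(a, b):
        raise ValueError("cannot merge non-overlapping annotations")
    if a.entity_type != "Gene" or b.entity_type != "Gene":
        raise ValueError("merging is defined for Gene annotations only")

    def key(ann: EntityAnnotation) -> tuple:
        # lower tuple wins: missing ids last, then priority rank, then span
        # length (longer first), then smaller id
        return (
            ann.norm_id == "",
            priority.rank(ann.source),
            -(ann.end - ann.start),
            ann.norm_id,
        )

    winner = min((a, b), key=key)
    return EntityAnnotation(
        doc_id=a.doc_id,
        start=min(a.start, b.start),
        end=max(a.end, b.end),
        surface=_stitch_surface(a, b),
        entity_type="Gene",
        norm_id=winner.norm_id,
        source=winner.source,
    )


def _merge_to_fixpoint(
    genes: list[EntityAnnotation], priority: PriorityOrder
) -> list[EntityAnnotation]:
    """Deterministic pairwise merging until no two gene spans overlap.

    Annotations are sorted by (start, -length) and swept left to right; the
    sweep repeats until stable, so chains A–B–C collapse into one span.
    """
    current = sorted(genes, key=lambda x: (x.start, -(x.end - x.start), x.norm_id, x.source))
    while True:
        merged: list[EntityAnnotation] = []
        changed = False
        for ann in current:
            if merged and max(merged[-1].start, ann.start) < min(merged[-1].end, ann.end):
                merged[-1] = merge_overlapping(merged[-1], ann, priority)
                changed = True
            else:
                merged.append(ann)
        current = merged
        if not changed:
            return current


def ensemble_merge(
    task_set: set[EntityAnnotation],
    gnorm_set: set[EntityAnnotation],
    pubtator_set: set[EntityAnnotation],
    priority: PriorityOrder = PriorityOrder(),
) -> set[EntityAnnotation]:
    """Merge annotation sets from the three annotators.

    All non-gene annotations (mutations, species, chemicals) pass through
    unchanged; overlapping gene annotations are merged pairwise to fixpoint,
    so the output contains no two overlapping gene annotations per document.
    """
    everything = task_set | gnorm_set | pubtator_set
    result = {a for a in everything if a.entity_type != "Gene"}
    genes_by_doc: dict[str, list[EntityAnnotation]] = {}
    for ann in everything:
        if ann.entity_type == "Gene":
            genes_by_doc.setdefault(ann.doc_id, []).append(ann)
    for doc_genes in genes_by_doc.values():
        result.update(_merge_to_fixpoint(doc_genes, priority))
    return result


def max_achievable_recall(
    relations: set[RelationAnnotation],
    annotations: set[EntityAnnotation],
) -> float:
    """Upper bound on relation-extraction recall under an annotation scheme.

    A gold pair is reachable only when both of its gene ids occur among the
    gene annotations of the same document; the returned value is the reachable
    fraction of gold pairs.
    """
    if not relations:
        logger.warning("max_achievable_recall of an empty relation set is defined as 1.0")
        return 1.0
    ids_by_doc: dict[str, set[str]] = {}
    for ann in annotations:
        if ann.entity_type == "Gene" and ann.norm_id:
            ids_by_doc.setdefault(ann.doc_id, set()).add(ann.norm_id)
    reachable = sum(
        1
        for rel in relations
        if set(rel.pair) <= ids_by_doc.get(rel.doc_id, set())
    )
    return reachable / len(relations)
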