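"""Evaluation metrics for triage and relation extraction.

Triage is scored as a ranked retrieval problem (mean average precision over
the relevant documents, here called ranked precision) plus the usual binary
precision/recall/F1.  Relation extraction is scored micro-averaged over
unordered normalized gene-id pairs pooled across documents.  A two-sample
z-test quantifies corpus shift in per-document entity counts, and a coverage
table summarizes which detector perspective (tools vs term lists) found
mutation evidence in each document class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .corpus_io import RelationAnnotation


@dataclass(frozen=True)
class Metrics:
    ranked_precision: float
    precision: float
    recall: float
    f1: float

    def __post_init__(self) -> None:
        p, r = self.precision, self.recall
        expected = 2 * p * r / (p + r) if p + r > 0 else 0.0
        if abs(self.f1 - expected) > 1e-9:
            raise ValueError("f1 inconsistent with precision and recall")


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def triage_metrics(
    ranking: Sequence[tuple[str, int]],
    labels: Mapping[str, int],
) -> Metrics:
    """Score a ranked triage run.

    ``ranking`` is the ordered list of ``(doc_id, predicted_label)`` with the
    most relevant-looking document first.  Ranked precision is the mean over
    all relevant documents of precision at that document's rank (standard MAP,
    counting every relevant document in the denominator).
    """
    for doc_id, _pred in ranking:
        if doc_id not in labels:
            raise ValueError(f"ranked document {doc_id!r} has no label")
    n_relevant = sum(1 for doc_id, _ in ranking if labels[doc_id] == 1)
    if n_relevant == 0:
        raise ValueError("ranked precision is undefined without relevant documents")

    hits = 0
    ap_sum = 0.0
    tp = fp = fn = 0
    for rank, (doc_id, pred) in enumerate(ranking, start=1):
        rel = labels[doc_id] == 1
        if rel:
            hits += 1
            ap_sum += hits / rank
        if pred == 1 and rel:
            tp += 1
        elif pred == 1:
            fp += 1
        elif rel:
            fn += 1
    p, r, f = _prf(tp, fp, fn)
    return Metrics(ap_sum / n_relevant, p, r, f)


def precision_at_k(
    ranking: Sequence[tuple[str, int]], labels: Mapping[str, int], k: int
) -> float:
    """Fraction of relevant documents among the top ``k`` ranks."""
    if k <= 0:
        raise ValueError("k must be positive")
    top = ranking[:k]
    return sum(1 for doc_id, _ in top if labels[doc_id] == 1) / len(top)


def micro_prf(
    predicted: Mapping[str, Iterable[RelationAnnotation | tuple[str, str]]],
    gold: Mapping[str, Iterable[RelationAnnotation | tuple[str, str]]],
) -> tuple[float, float, float]:
    """Micro-averaged P/R/F over unordered id pairs pooled across documents."""

    def pairs(items) -> set[tuple[str, str]]:
        out = set()
        for item in items:
            pair = item.pair if isinstance(item, RelationAnnotation) else tuple(item)
            out.add(tuple(sorted(pair)))
        return out

    tp = fp = fn = 0
    for doc_id in set(predicted) | set(gold):
        pred = pairs(predicted.get(doc_id, ()))
        ref = pairs(gold.get(doc_id, ()))
        tp += len(pred & ref)
        fp += len(pred - ref)
        fn += len(ref - pred)
    return _prf(tp, fp, fn)


def two_sample_ztest(
    sample_a: Sequence[float], sample_b: Sequence[float]
) -> tuple[float, float]:
    """Two-tailed two-sample z-test on per-document counts.

    ``z = (mean_a - mean_b) / sqrt(var_a/n_a + var_b/n_b)`` with sample
    variances (n-1 denominator); the p-value is the two-tailed normal tail
    mass.  Requires at least 30 observations per sample.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 30 or len(b) < 30:
        raise ValueError(
            "z-test requires n >= 30 per sample; use a t-test for smaller samples"
        )
    se = np.sqrt(a.var(ddof=1) / len(a) + b.var(ddof=1) / len(b))
    if se == 0:
        return 0.0, 1.0
    z = (a.mean() - b.mean()) / se
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def detection_coverage(
    labels: Mapping[str, int],
    evidence: Mapping[str, Mapping[str, bool]],
) -> dict[int, dict[str, float]]:
    """Per-class fractions of documents with mutation evidence by perspective.

    ``evidence[doc] = {"tools": bool, "terms": bool}``.  For each label class
    the fractions of documents detected by tools only, terms only, both and
    neither are returned; they sum to 1 per class.
    """
    by_class: dict[int, list[str]] = {}
    for doc_id, label in labels.items():
        by_class.setdefault(label, []).append(doc_id)
    table: dict[int, dict[str, float]] = {}
    for label, docs in sorted(by_class.items()):
        if not docs:
            raise ValueError(f"class {label} has no documents")
        counts = {"tools_only": 0, "terms_only": 0, "both": 0, "neither": 0}
        for doc_id in docs:
            ev = evidence.get(doc_id, {})
            tools = bool(ev.get("tools"))
            terms = bool(ev.get("terms"))
            if tools and terms:
                counts["both"] += 1
            elif tools:
                counts["tools_only"] += 1
            elif terms:
                counts["terms_only"] += 1
            else:
                counts["neither"] += 1
        table[label] = {k: c / len(docs) for k, c in counts.items()}
    if not table:
        raise ValueError("no labelled documents")
    return table
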