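"""Document-level feature engineering for PPIm triage.

Each document yields 27 named features (F1–F27) built from four aspects:
structure (paragraph vs sentence vs 2-sentence window), perspective (term
lists vs annotation tools vs both), occurrence (individual, mutation +
interaction co-occurrence, mutation + degree + interaction triplet) and count
(total vs unique, plus two probability features).  A tf-idf block over
processed tokens provides the lexical baseline.

A sentence counts as containing a *tool interaction* when at least two
distinct tool-annotated genes occur in it; tool mutations are Mutation
annotations.  Term-list matches come from :mod:`ppimine.term_matching`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus_io import Document, EntityAnnotation
from .term_matching import TermMatch, porter_stem, stem_tokens

logger = logging.getLogger(__name__)

FEATURE_NAMES = tuple(f"F{i}" for i in range(1, 28))

#: cumulative feature groups used by the contribution study
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "S1": ("F1", "F2", "F3", "F4"),
    "S2": ("F5", "F6"),
    "S3": ("F7", "F8", "F9", "F10", "F11"),
    "S4": ("F12",),
    "S5": ("F13", "F14"),
    "S6": ("F15",),
    "S7": ("F16", "F17"),
    "S8": ("F18",),
    "S9": ("F19", "F20"),
    "S10": ("F21", "F22", "F23"),
    "S11": ("F24", "F25", "F26", "F27"),
}

COUNT_FEATURES = tuple(n for n in FEATURE_NAMES if n not in ("F11", "F27"))


@dataclass(frozen=True)
class ImpactConfig:
    """Weights of the mutation and interaction components of the impact score."""

    alpha: float = 0.5
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.alpha <= 1 and 0 <= self.beta <= 1):
            raise ValueError("alpha and beta must lie in [0, 1]")
        if abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValueError("alpha + beta must equal 1")


def impact_score(
    mut_total: int,
    int_total: int,
    doc_max_mut: int,
    doc_max_int: int,
    cfg: ImpactConfig = ImpactConfig(),
) -> float:
    """Impact of a sentence or window from co-occurring mention totals.

    Zero when either total is zero (no mutation–interaction co-occurrence);
    otherwise the weighted sum of the totals, each normalized by the
    document-wide maximum of that total, keeping the score in [0, 1].
    """
    if mut_total == 0 or int_total == 0:
        return 0.0
    if doc_max_mut <= 0 or doc_max_int <= 0:
        raise ValueError("document maximum is zero while a total is positive")
    if mut_total > doc_max_mut or int_total > doc_max_int:
        raise ValueError("totals exceed their document maxima")
    return cfg.alpha * (mut_total / doc_max_mut) + cfg.beta * (int_total / doc_max_int)


@dataclass
class FeatureVector:
    values: dict[str, float]
    label: int | None = None

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self, names: Sequence[str] = FEATURE_NAMES) -> np.ndarray:
        return np.array([self.values[n] for n in names], dtype=float)

    def validate(self) -> None:
        v = self.values
        for name in COUNT_FEATURES:
            x = v[name]
            if x < 0 or x != int(x):
                raise ValueError(f"{name} must be a non-negative integer, got {x}")
        for name in ("F11", "F27"):
            if not 0.0 <= v[name] <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v[name]}")
        checks = [
            ("F2 <= F1", v["F2"] <= v["F1"]),
            ("F4 <= F3", v["F4"] <= v["F3"]),
            ("F15 <= min(F13, F14)", v["F15"] <= min(v["F13"], v["F14"])),
            ("F18 <= min(F16, F17)", v["F18"] <= min(v["F16"], v["F17"])),
            ("F19 >= max(F15, F18)", v["F19"] >= max(v["F15"], v["F18"])),
            ("F19 <= F15 + F18", v["F19"] <= v["F15"] + v["F18"]),
        ]
        for desc, ok in checks:
            if not ok:
                raise ValueError(f"feature invariant violated: {desc}")


def build_triage_features(
    doc: Document,
    gene_annotations: Iterable[EntityAnnotation],
    mutation_annotations: Iterable[EntityAnnotation],
    term_matches: Iterable[TermMatch],
    pie_score: float | None = None,
    cfg: ImpactConfig = ImpactConfig(),
) -> FeatureVector:
    """Build the F1–F27 vector for one sentence-segmented document."""
    if not doc.sentences:
        doc.segment()
    n_sent = len(doc.sentences)

    # per-sentence tallies
    term_int = [0] * n_sent
    term_mut = [0] * n_sent
    term_deg = [0] * n_sent
    tool_mut = [0] * n_sent
    tool_gene_ids: list[set[str]] = [set() for _ in range(n_sent)]
    tool_gene_count = [0] * n_sent

    int_terms_seen: set[str] = set()
    mut_terms_seen: set[str] = set()

    for m in term_matches:
        i = m.sentence_index
        if not 0 <= i < n_sent:
            continue
        if m.category == "interaction":
            term_int[i] += 1
            int_terms_seen.add(m.term)
        elif m.category in ("strong_mutation", "weak_mutation"):
            term_mut[i] += 1
            mut_terms_seen.add(m.term)
        elif m.category == "degree":
            term_deg[i] += 1

    gene_ids_seen: set[str] = set()
    n_gene_total = 0
    mut_surfaces_seen: set[str] = set()
    n_mut_total = 0
    for ann in gene_annotations:
        i = doc.sentence_index_of(ann.start)
        n_gene_total += 1
        key = ann.norm_id or ann.surface.lower()
        gene_ids_seen.add(key)
        if i >= 0:
            tool_gene_ids[i].add(key)
            tool_gene_count[i] += 1
    for ann in mutation_annotations:
        i = doc.sentence_index_of(ann.start)
        n_mut_total += 1
        mut_surfaces_seen.add(ann.surface.lower())
        if i >= 0:
            tool_mut[i] += 1

    tool_int_flag = [len(ids) >= 2 for ids in tool_gene_ids]

    v: dict[str, float] = {}
    # paragraph level, term lists
    v["F1"] = sum(term_int)
    v["F2"] = len(int_terms_seen)
    v["F3"] = sum(term_mut)
    v["F4"] = len(mut_terms_seen)
    cooc_terms = v["F1"] > 0 and v["F3"] > 0
    v["F5"] = v["F1"] + v["F3"] if cooc_terms else 0
    v["F6"] = v["F2"] + v["F4"] if cooc_terms else 0
    # paragraph level, tools
    v["F7"] = n_gene_total
    v["F8"] = len(gene_ids_seen)
    v["F9"] = n_mut_total
    v["F10"] = len(mut_surfaces_seen)
    if pie_score is None:
        logger.warning("doc %s: no interaction-probability score; F11 defaults to 0", doc.doc_id)
        v["F11"] = 0.0
    else:
        v["F11"] = float(pie_score)
    tool_int_para = sum(tool_int_flag)
    v["F12"] = tool_int_para + n_mut_total if tool_int_para > 0 and n_mut_total > 0 else 0

    # sentence level
    v["F13"] = sum(1 for x in term_mut if x > 0)
    v["F14"] = sum(1 for x in term_int if x > 0)
    v["F15"] = sum(1 for i in range(n_sent) if term_mut[i] > 0 and term_int[i] > 0)
    v["F16"] = sum(1 for x in tool_mut if x > 0)
    v["F17"] = sum(1 for x in tool_gene_count if x > 0)
    v["F18"] = sum(1 for i in range(n_sent) if tool_mut[i] > 0 and tool_int_flag[i])
    v["F19"] = sum(
        1
        for i in range(n_sent)
        if (term_mut[i] > 0 and term_int[i] > 0) or (tool_mut[i] > 0 and tool_int_flag[i])
    )

    def complement(i: int) -> bool:
        return (term_mut[i] > 0 and tool_int_flag[i]) or (tool_mut[i] > 0 and term_int[i] > 0)

    def union_mut(i: int) -> bool:
        return term_mut[i] > 0 or tool_mut[i] > 0

    def union_int(i: int) -> bool:
        return term_int[i] > 0 or tool_int_flag[i]

    v["F20"] = sum(1 for i in range(n_sent) if complement(i))
    v["F21"] = sum(
        1 for i in range(n_sent) if term_mut[i] > 0 and term_deg[i] > 0 and term_int[i] > 0
    )
    v["F22"] = sum(
        1 for i in range(n_sent) if union_mut(i) and union_int(i) and term_deg[i] > 0
    )
    v["F23"] = sum(1 for i in range(n_sent) if complement(i) and term_deg[i] > 0)

    # sentence 2-gram windows
    windows = list(range(n_sent - 1))

    def wsum(values: list[int], w: int) -> int:
        return values[w] + values[w + 1]

    def wany(flags: list[bool], w: int) -> bool:
        return flags[w] or flags[w + 1]

    v["F24"] = sum(
        1
        for w in windows
        if wsum(term_mut, w) > 0 and wsum(term_deg, w) > 0 and wsum(term_int, w) > 0
    )
    v["F25"] = sum(
        1
        for w in windows
        if (wsum(term_mut, w) > 0 or wsum(tool_mut, w) > 0)
        and (wsum(term_int, w) > 0 or wany(tool_int_flag, w))
        and wsum(term_deg, w) > 0
    )
    complement_windows = [
        w
        for w in windows
        if wsum(term_deg, w) > 0
        and (
            (wsum(term_mut, w) > 0 and wany(tool_int_flag, w))
            or (wsum(tool_mut, w) > 0 and wsum(term_int, w) > 0)
        )
    ]
    v["F26"] = len(complement_windows)

    # F27: mean impact over the complement-triplet windows counted by F26
    win_mut = [wsum(term_mut, w) + wsum(tool_mut, w) for w in windows]
    win_int = [wsum(term_int, w) + int(tool_int_flag[w]) + int(tool_int_flag[w + 1]) for w in windows]
    max_mut = max(win_mut, default=0)
    max_int = max(win_int, default=0)
    if complement_windows:
        v["F27"] = float(
            np.mean([impact_score(win_mut[w], win_int[w], max_mut, max_int, cfg) for w in complement_windows])
        )
    else:
        v["F27"] = 0.0

    vec = FeatureVector({n: float(v[n]) for n in FEATURE_NAMES})
    vec.validate()
    return vec


def corpus_feature_vectors(
    bundle, term_lists=None, cfg: ImpactConfig = ImpactConfig()
) -> tuple[list[FeatureVector], list[str]]:
    """Build one feature vector per document of a corpus bundle.

    Term matching uses the packaged default trigger lists unless ``term_lists``
    is given.  Returns vectors and doc ids in corpus order.
    """
    from .term_matching import find_trigger_mentions, load_term_lists

    lists = term_lists if term_lists is not None else load_term_lists()
    vectors: list[FeatureVector] = []
    doc_ids: list[str] = []
    for doc in bundle.documents:
        anns = bundle.annotations_for(doc.doc_id)
        genes = [a for a in anns if a.entity_type == "Gene"]
        muts = [a for a in anns if a.entity_type == "Mutation"]
        matches = find_trigger_mentions(doc, lists)
        vectors.append(
            build_triage_features(
                doc, genes, muts, matches, bundle.scores.get(doc.doc_id), cfg
            )
        )
        doc_ids.append(doc.doc_id)
    return vectors, doc_ids


def features_to_frame(
    vectors: Sequence[FeatureVector], doc_ids: Sequence[str]
) -> pd.DataFrame:
    """Assemble vectors into a doc-indexed DataFrame with F1..F27 columns."""
    if len(vectors) != len(doc_ids):
        raise ValueError("vectors and doc_ids differ in length")
    frame = pd.DataFrame(
        [[vec.values[n] for n in FEATURE_NAMES] for vec in vectors],
        index=list(doc_ids),
        columns=list(FEATURE_NAMES),
    )
    frame.index.name = "doc_id"
    return frame


def write_feature_table(frame: pd.DataFrame, labels: dict[str, int], stream: IO[str]) -> None:
    """Export the feature matrix as TSV with a trailing label column."""
    out = frame.copy()
    out["label"] = [labels.get(d, "") for d in out.index]
    out.to_csv(stream, sep="\t")


# ---------------------------------------------------------------------------
# tf-idf block
# ---------------------------------------------------------------------------

# compact English stop-word list; punctuation never survives tokenization
_STOP_WORDS = frozenset(
    """a about above after again all also an and any are as at be because been
    before being below between both but by could did do does doing down during
    each few for from further had has have having here how i if in into is it
    its itself more most no nor not of off on once only or other our out over
    own same should so some such than that the their them then there these
    they this those through to too under until up very was we were what when
    where which while who whom why will with would""".split()
)


def _analyze(text: str) -> list[str]:
    """Case-fold, tokenize, drop stop words and numerals, stem."""
    out = []
    for token, _stem, _span in stem_tokens(text.lower()):
        if token in _STOP_WORDS or token.isdigit():
            continue
        out.append(porter_stem(token))
    return out


def build_tfidf(
    texts: Sequence[str], min_df: int = 1, max_features: int | None = 20000
) -> tuple:
    """Fit a tf-idf matrix over processed tokens.

    Returns ``(matrix, vectorizer)``; the fitted vectorizer carries the
    vocabulary and idf statistics, so held-out documents are transformed with
    training statistics only (out-of-vocabulary tokens contribute nothing).
    """
    if len(texts) == 0:
        raise ValueError("corpus is empty")
    vectorizer = TfidfVectorizer(
        analyzer=_analyze, min_df=min_df, max_features=max_features
    )
    matrix = vectorizer.fit_transform(texts)
    if len(vectorizer.vocabulary_) == 0:
        raise ValueError("tf-idf vocabulary is empty")
    return matrix, vectorizer
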