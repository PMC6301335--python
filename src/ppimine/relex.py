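"""Machine-learning PPIm relation extraction over dependency graphs.

The pipeline casts document-level relation extraction as binary
classification of candidate gene-mention pairs.  Same-sentence pairs use the
dependency graph of that sentence; cross-sentence pairs use the two sentence
graphs joined by a special root-to-root edge.  The two argument mentions are
masked as ``Protein1``/``Protein2`` and other annotated entities as
``Protein_Other``/``Mutation_Other``/``Species_Other``/``Chemical_Other``
before feature extraction, so the classifier generalizes across gene names.

Graph features are an explicit map (bags of node labels and labelled edges,
plus the labelled shortest path between the two argument nodes) hashed into a
fixed-width sparse vector; two linear hinge-loss classifiers, one for
sentence-level and one for cross-sentence candidates, are trained with
asymmetric class weights and their positive predictions are unioned into
document-level id pairs.

Dependency graphs may be supplied from pre-parsed CoNLL-U; absent a parse, a
deterministic token chain graph (token i -> i+1, label "next") keeps the
pipeline runnable parser-free.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from sklearn.feature_extraction import FeatureHasher
from sklearn.linear_model import SGDClassifier

from .corpus_io import (
    Document,
    EntityAnnotation,
    RelationAnnotation,
    canonical_pair,
)
from .term_matching import TermMatch, stem_tokens

logger = logging.getLogger(__name__)

SENT_LINK = "SENT_LINK"

_MASK_BY_TYPE = {
    "Gene": "Protein_Other",
    "Mutation": "Mutation_Other",
    "Species": "Species_Other",
    "Chemical": "Chemical_Other",
}


# ---------------------------------------------------------------------------
# dependency graphs
# ---------------------------------------------------------------------------

@dataclass
class DepGraph:
    """Directed dependency graph with labelled nodes and edges.

    Node attributes: ``label`` (token or mask string) and ``span`` (absolute
    character offsets).  Edge attribute: ``label`` (dependency relation).
    """

    graph: nx.DiGraph
    root: int

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() == 0:
            raise ValueError("dependency graph has no nodes")
        if self.root not in self.graph:
            raise ValueError(f"root {self.root} is not a node")
        if not nx.is_weakly_connected(self.graph):
            raise ValueError("dependency graph is not connected")

    def copy(self) -> "DepGraph":
        return DepGraph(self.graph.copy(), self.root)

    def node_label(self, node: int) -> str:
        return self.graph.nodes[node]["label"]

    def nodes_overlapping(self, start: int, end: int) -> list[int]:
        return [
            n
            for n, data in self.graph.nodes(data=True)
            if data.get("span") and max(data["span"][0], start) < min(data["span"][1], end)
        ]


def build_chain_graph(sentence: str, offset: int = 0) -> DepGraph:
    """Fallback parse: tokens chained left to right with edge label "next"."""
    tokens = stem_tokens(sentence)
    g = nx.DiGraph()
    if not tokens:
        g.add_node(0, label="<empty>", span=(offset, offset + max(len(sentence), 1)))
        return DepGraph(g, 0)
    for i, (token, _stem, (s, e)) in enumerate(tokens):
        g.add_node(i, label=token, span=(offset + s, offset + e))
    for i in range(len(tokens) - 1):
        g.add_edge(i, i + 1, label="next")
    return DepGraph(g, 0)


def sentence_graphs(
    doc: Document, parses: Sequence[DepGraph] | None = None
) -> list[DepGraph]:
    """One graph per sentence: supplied parses, else fallback chain graphs."""
    if not doc.sentences:
        doc.segment()
    if parses is not None:
        if len(parses) != len(doc.sentences):
            raise ValueError(
                f"doc {doc.doc_id}: {len(parses)} parses for {len(doc.sentences)} sentences"
            )
        return list(parses)
    return [
        build_chain_graph(doc.text[span.start:span.end], span.start)
        for span in doc.sentences
    ]


def read_conllu(stream: IO[str] | Iterable[str], doc: Document) -> list[DepGraph]:
    """Build per-sentence graphs from CoNLL-U, aligning token spans to text.

    Tokens are located by sequential search inside each sentence span, so the
    tokenization must be consistent with the document text.
    """
    if not doc.sentences:
        doc.segment()
    blocks: list[list[list[str]]] = [[]]
    for line in stream:
        line = line.rstrip("\n")
        if not line.strip():
            if blocks[-1]:
                blocks.append([])
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if "-" in cols[0] or "." in cols[0]:
            continue  # multiword/empty tokens
        blocks[-1].append(cols)
    blocks = [b for b in blocks if b]
    if len(blocks) != len(doc.sentences):
        raise ValueError(
            f"doc {doc.doc_id}: {len(blocks)} parsed sentences for "
            f"{len(doc.sentences)} segmented sentences"
        )
    graphs = []
    for block, span in zip(blocks, doc.sentences):
        g = nx.DiGraph()
        cursor = span.start
        root = None
        for cols in block:
            idx = int(cols[0]) - 1
            form, head, deprel = cols[1], int(cols[6]), cols[7]
            pos = doc.text.find(form, cursor, span.end)
            token_span = (pos, pos + len(form)) if pos != -1 else None
            if token_span:
                cursor = token_span[1]
            g.add_node(idx, label=form, span=token_span)
            if head == 0:
                root = idx
            else:
                g.add_edge(head - 1, idx, label=deprel)
        if root is None:
            raise ValueError(f"doc {doc.doc_id}: CoNLL-U sentence lacks a root")
        graphs.append(DepGraph(g, root))
    return graphs


def join_graphs(g1: DepGraph, g2: DepGraph) -> DepGraph:
    """Connect two sentence graphs with a root-to-root ``SENT_LINK`` edge."""
    joined = nx.DiGraph()
    for n, data in g1.graph.nodes(data=True):
        joined.add_node(("a", n), **data)
    for n, data in g2.graph.nodes(data=True):
        joined.add_node(("b", n), **data)
    for u, v, data in g1.graph.edges(data=True):
        joined.add_edge(("a", u), ("a", v), **data)
    for u, v, data in g2.graph.edges(data=True):
        joined.add_edge(("b", u), ("b", v), **data)
    joined.add_edge(("a", g1.root), ("b", g2.root), label=SENT_LINK)
    return DepGraph(joined, ("a", g1.root))


# ---------------------------------------------------------------------------
# candidate pairs
# ---------------------------------------------------------------------------

@dataclass
class CandidatePair:
    doc_id: str
    mention_a: EntityAnnotation
    mention_b: EntityAnnotation
    id_pair: tuple[str, str]
    sentence_indices: tuple[int, int]
    is_sentence_level: bool
    graph: DepGraph
    label: int | None = None

    def __post_init__(self) -> None:
        i, j = self.sentence_indices
        if self.is_sentence_level != (i == j):
            raise ValueError("is_sentence_level inconsistent with sentence indices")


def generate_candidate_pairs(
    doc: Document,
    gene_annotations: Iterable[EntityAnnotation],
    graphs: Sequence[DepGraph] | None = None,
    all_annotations: Iterable[EntityAnnotation] = (),
    max_sentence_distance: int | None = 3,
) -> list[CandidatePair]:
    """All unordered gene-mention pairs of a document, with masked graphs.

    Cross-sentence pairs beyond ``max_sentence_distance`` sentences apart are
    skipped (``None`` lifts the cap).  Self-id pairs are generated here and
    removed later by :func:`filter_self_relations`.
    """
    graphs = sentence_graphs(doc, graphs)
    mentions = sorted(gene_annotations, key=lambda a: (a.start, a.end))
    located: list[tuple[EntityAnnotation, int]] = []
    for m in mentions:
        idx = doc.sentence_index_of(m.start)
        if idx < 0:
            raise ValueError(
                f"doc {doc.doc_id}: gene mention at {m.start} lies outside every sentence"
            )
        located.append((m, idx))

    other_annotations = list(all_annotations)
    pairs: list[CandidatePair] = []
    for (a, ia), (b, ib) in itertools.combinations(located, 2):
        if max(a.start, b.start) < min(a.end, b.end):
            continue  # overlapping mentions are one entity, not a pair
        if max_sentence_distance is not None and abs(ib - ia) > max_sentence_distance:
            continue
        if ia == ib:
            graph = graphs[ia].copy()
        else:
            graph = join_graphs(graphs[min(ia, ib)], graphs[max(ia, ib)])
        pair = CandidatePair(
            doc_id=doc.doc_id,
            mention_a=a,
            mention_b=b,
            id_pair=canonical_pair(a.norm_id, b.norm_id) if a.norm_id and b.norm_id else (a.norm_id, b.norm_id),
            sentence_indices=(ia, ib),
            is_sentence_level=ia == ib,
            graph=graph,
        )
        pair.graph = mask_entities(pair, other_annotations)
        pairs.append(pair)
    return pairs


def mask_entities(
    pair: CandidatePair, all_annotations: Iterable[EntityAnnotation]
) -> DepGraph:
    """Relabel argument and bystander entity nodes with generic strings.

    The two argument mentions become ``Protein1`` and ``Protein2`` (ordered by
    document offset); any other annotation overlapping a node is masked by its
    entity type.  Topology is never changed, only labels.
    """
    masked = pair.graph.copy()
    first, second = sorted(
        (pair.mention_a, pair.mention_b), key=lambda m: (m.start, m.end)
    )
    arg_nodes: set = set()
    for mention, mask in ((first, "Protein1"), (second, "Protein2")):
        nodes = masked.nodes_overlapping(mention.start, mention.end)
        if not nodes:
            raise ValueError(
                f"doc {pair.doc_id}: mention {mention.surface!r} at "
                f"({mention.start}, {mention.end}) aligns to no graph node"
            )
        for n in nodes:
            masked.graph.nodes[n]["label"] = mask
        arg_nodes.update(nodes)
    for ann in all_annotations:
        if ann.doc_id != pair.doc_id:
            continue
        mask = _MASK_BY_TYPE.get(ann.entity_type)
        if mask is None:
            continue
        for n in masked.nodes_overlapping(ann.start, ann.end):
            if n not in arg_nodes:
                masked.graph.nodes[n]["label"] = mask
    return masked


def filter_self_relations(items: Iterable) -> list:
    """Drop candidates or relations whose two normalized ids are identical."""
    kept = []
    for item in items:
        pair = item.id_pair if isinstance(item, CandidatePair) else item.pair
        if pair[0] == pair[1]:
            continue
        kept.append(item)
    return kept


def label_candidates(
    pairs: Iterable[CandidatePair],
    gold: set[RelationAnnotation],
) -> tuple[list[CandidatePair], dict[tuple[bool, int], int]]:
    """Label each candidate by gold-pair lookup on canonical id pairs.

    Returns the labelled candidates and a count table keyed by
    ``(is_sentence_level, label)``.
    """
    gold_pairs = {(r.doc_id, r.pair) for r in gold}
    labelled = []
    counts: dict[tuple[bool, int], int] = {}
    for pair in pairs:
        key = (pair.doc_id, canonical_pair(*pair.id_pair))
        label = 1 if key in gold_pairs else 0
        labelled.append(replace_label(pair, label))
        cell = (pair.is_sentence_level, label)
        counts[cell] = counts.get(cell, 0) + 1
    return labelled, counts


def replace_label(pair: CandidatePair, label: int) -> CandidatePair:
    return CandidatePair(
        pair.doc_id, pair.mention_a, pair.mention_b, pair.id_pair,
        pair.sentence_indices, pair.is_sentence_level, pair.graph, label,
    )


# ---------------------------------------------------------------------------
# graph feature map (substitute for a subgraph-matching kernel)
# ---------------------------------------------------------------------------

def graph_features(masked: DepGraph) -> dict[str, float]:
    """Explicit feature map of a masked candidate graph.

    Bags of node labels, bags of labelled edges ``(head, relation, dependent)``
    and the labelled shortest-path label sequence between the ``Protein1`` and
    ``Protein2`` nodes (over the undirected graph).  Deterministic: identical
    graphs give identical mappings.
    """
    g = masked.graph
    features: dict[str, float] = {}
    p1_nodes = [n for n, d in g.nodes(data=True) if d["label"] == "Protein1"]
    p2_nodes = [n for n, d in g.nodes(data=True) if d["label"] == "Protein2"]
    if not p1_nodes or not p2_nodes:
        raise ValueError("masked graph lacks Protein1/Protein2 nodes")
    for _n, data in g.nodes(data=True):
        key = f"node:{data['label'].lower()}"
        features[key] = features.get(key, 0.0) + 1.0
    for u, v, data in g.edges(data=True):
        key = (
            f"edge:{g.nodes[u]['label'].lower()}>{data.get('label', '')}"
            f">{g.nodes[v]['label'].lower()}"
        )
        features[key] = features.get(key, 0.0) + 1.0
    und = g.to_undirected(as_view=True)
    try:
        path = nx.shortest_path(und, p1_nodes[0], p2_nodes[0])
        labels = [g.nodes[n]["label"].lower() for n in path]
        features["path:" + ">".join(labels)] = 1.0
        features["pathlen"] = float(len(path) - 1)
    except nx.NetworkXNoPath:  # pragma: no cover - graphs are connected
        features["path:none"] = 1.0
    return features


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelexModelConfig:
    """Configuration of the two-pipeline candidate classifier.

    Class weights up-weight the positive class: 2:1 for the sentence-level
    pipeline, 6:1 for the sparser cross-sentence pipeline.
    """

    class_weight_sentence: float = 2.0
    class_weight_nonsentence: float = 6.0
    use_relevance_feature: bool = False
    use_mutation_terms: bool = False
    n_hash_features: int = 2 ** 16

    def __post_init__(self) -> None:
        if self.class_weight_sentence <= 0 or self.class_weight_nonsentence <= 0:
            raise ValueError("class-weight ratios must be positive")


@dataclass
class RelexModel:
    cfg: RelexModelConfig
    hasher: FeatureHasher
    sentence_clf: SGDClassifier | None = None
    nonsentence_clf: SGDClassifier | None = None


def _candidate_features(
    pair: CandidatePair,
    cfg: RelexModelConfig,
    relevance_scores: Mapping[str, float] | None,
    term_matches: Mapping[str, Sequence[TermMatch]] | None,
) -> dict[str, float]:
    features = graph_features(pair.graph)
    if cfg.use_relevance_feature:
        score = (relevance_scores or {}).get(pair.doc_id, 0.0)
        features["doc_relevance"] = float(score)
    if cfg.use_mutation_terms and term_matches:
        scope = set(range(min(pair.sentence_indices), max(pair.sentence_indices) + 1))
        for m in term_matches.get(pair.doc_id, ()):
            if m.sentence_index in scope and m.category in (
                "strong_mutation", "weak_mutation",
            ):
                key = f"mterm:{m.term}"
                features[key] = features.get(key, 0.0) + 1.0
    return features


def train_relex(
    pairs: Sequence[CandidatePair],
    cfg: RelexModelConfig = RelexModelConfig(),
    seed: int = 0,
    relevance_scores: Mapping[str, float] | None = None,
    term_matches: Mapping[str, Sequence[TermMatch]] | None = None,
) -> RelexModel:
    """Train the sentence and non-sentence hinge-loss classifiers.

    Candidates must be labelled.  An empty or single-class stream disables
    that pipeline with a warning.
    """
    hasher = FeatureHasher(n_features=cfg.n_hash_features)
    model = RelexModel(cfg, hasher)
    streams = {
        True: [p for p in pairs if p.is_sentence_level],
        False: [p for p in pairs if not p.is_sentence_level],
    }
    for sentence_level, stream in streams.items():
        name = "sentence" if sentence_level else "non-sentence"
        labels = [p.label for p in stream]
        if any(l is None for l in labels):
            raise ValueError("candidates must be labelled before training")
        if not stream or len(set(labels)) < 2:
            logger.warning("%s pipeline disabled: insufficient training data", name)
            continue
        weight = (
            cfg.class_weight_sentence if sentence_level else cfg.class_weight_nonsentence
        )
        clf = SGDClassifier(
            loss="hinge",
            class_weight={1: weight, 0: 1.0},
            random_state=seed,
            max_iter=1000,
            tol=1e-3,
        )
        X = hasher.transform(
            _candidate_features(p, cfg, relevance_scores, term_matches) for p in stream
        )
        clf.fit(X, np.array(labels))
        if sentence_level:
            model.sentence_clf = clf
        else:
            model.nonsentence_clf = clf
    return model


def extract_relations_ml(
    model: RelexModel,
    pairs: Sequence[CandidatePair],
    relevance_scores: Mapping[str, float] | None = None,
    term_matches: Mapping[str, Sequence[TermMatch]] | None = None,
) -> dict[str, set[RelationAnnotation]]:
    """Classify candidates and aggregate positives to document-level pairs.

    Self-id pairs are filtered before classification; positively classified
    mention pairs map to their canonical id pair, deduplicated per document.
    The output is invariant to candidate ordering.
    """
    usable = [
        p for p in filter_self_relations(pairs) if p.id_pair[0] and p.id_pair[1]
    ]
    out: dict[str, set[RelationAnnotation]] = {}
    for sentence_level, clf in ((True, model.sentence_clf), (False, model.nonsentence_clf)):
        stream = [p for p in usable if p.is_sentence_level == sentence_level]
        if not stream or clf is None:
            continue
        X = model.hasher.transform(
            _candidate_features(p, model.cfg, relevance_scores, term_matches)
            for p in stream
        )
        preds = clf.predict(X)
        for pair, pred in zip(stream, preds):
            if pred == 1:
                out.setdefault(pair.doc_id, set()).add(
                    RelationAnnotation(pair.doc_id, canonical_pair(*pair.id_pair))
                )
    return out
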