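"""Synthetic PPIm corpora with controllable class statistics.

The generator emulates the structure of a mutation-affected
protein-interaction (PPIm) triage/extraction corpus without any external
download: two document classes (relevant / non-relevant) whose per-document
tool-detectable mutation counts and interaction-term counts follow
class-conditional count distributions; relevant documents embed planted
gene-pair relations expressed in template sentences that combine the pair, an
interaction trigger, a point-mutation token and a degree term; gene mentions
carry synthetic numeric ids (disjoint from real NCBI identifiers) and can be
thinned with an independent per-annotation dropout to emulate imperfect
entity recognizers.

Default rates are the corpus statistics of the task this package models:
tool-mutation means 1.6744 (relevant) / 0.7046 (non-relevant) and interaction
means 15.6217 / 14.3366 for the training distribution, with a shifted test
distribution (2.6520 / 2.2517 mutation means) available through
:func:`corpus_shift_variant`.

Both classes draw from the same sentence-template vocabulary — non-relevant
documents may mention interactions, mutations and degree words, just never in
the planted pair-trigger-mutation configuration — so lexical features alone
are informative but imperfect, while co-occurrence features carry the
separating signal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .corpus_io import (
    CorpusBundle,
    Document,
    EntityAnnotation,
    RelationAnnotation,
    canonical_pair,
)

_AA1 = "ACDEFGHIKLMNPQRSTVWY"

#: shifted test-distribution mutation means
SHIFTED_MUTATION_RATES = {
    "mutation_rate_relevant": 2.6520,
    "mutation_rate_nonrelevant": 2.2517,
}


@dataclass(frozen=True)
class SynthConfig:
    n_docs: int = 100
    relevant_fraction: float = 0.42
    mutation_rate_relevant: float = 1.6744
    mutation_rate_nonrelevant: float = 0.7046
    interaction_rate_relevant: float = 15.6217
    interaction_rate_nonrelevant: float = 14.3366
    gene_inventory_size: int = 200
    relations_per_relevant_doc: int = 1
    relation_sentence_repeats: int = 3
    annotation_dropout: float = 0.0
    seed: int = 0
    # over-dispersion option: negative binomial matched to mean and variance
    count_distribution: str = "poisson"
    mutation_std_relevant: float = 2.6767
    mutation_std_nonrelevant: float = 1.6180
    interaction_std_relevant: float = 10.9309
    interaction_std_nonrelevant: float = 9.9784
    # realism noise: probability that a mutation sentence also mentions
    # binding (and, nested, a degree word); probability that it instead
    # reports a mutation modulating enzymatic activity on a random gene pair
    # (a near-miss that is not a PPIm relation); probability of a "no effect"
    # pair+mutation sentence in a non-relevant document
    cooccurrence_noise: float = 0.3
    degree_noise: float = 0.3
    pair_noise: float = 0.08
    negation_noise: float = 0.1
    distractor_pair_prob: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.relevant_fraction <= 1:
            raise ValueError("relevant_fraction must lie in [0, 1]")
        if not 0 <= self.annotation_dropout <= 1:
            raise ValueError("annotation_dropout must lie in [0, 1]")
        for name in (
            "mutation_rate_relevant", "mutation_rate_nonrelevant",
            "interaction_rate_relevant", "interaction_rate_nonrelevant",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.count_distribution not in ("poisson", "negbin"):
            raise ValueError("count_distribution must be 'poisson' or 'negbin'")
        if self.relation_sentence_repeats < 1 or self.relations_per_relevant_doc < 1:
            raise ValueError("relation settings must be >= 1")


def _draw_count(rng: np.random.Generator, mean: float, std: float, dist: str) -> int:
    if mean == 0:
        return 0
    if dist == "negbin" and std ** 2 > mean:
        var = std ** 2
        n = mean ** 2 / (var - mean)
        p = n / (n + mean)
        return int(rng.negative_binomial(n, p))
    return int(rng.poisson(mean))


# sentence templates; {A}/{B} are the planted pair, {VAR} a mutation token
_RELATION_TEMPLATES = (
    "{A} interacts with {B}, and this interaction is abolished by the {VAR} mutation.",
    "The {VAR} substitution markedly reduced binding of {A} to {B}.",
    "Binding of {A} to {B} was strongly impaired by the {VAR} variant.",
)

# each contributes exactly one interaction-term stem and nothing else
_INTERACTION_FILLERS = (
    "A stable complex was detected in the lysate.",
    "Phosphorylation levels were measured in the cells.",
    "Kinase activity was assayed in the crude extract.",
    "Receptor density was quantified in the membrane preparation.",
    "A direct interaction between the two partners was previously reported.",
)

_MUTATION_PLAIN = (
    "The {VAR} mutation was detected in several samples.",
    "A {VAR} substitution was identified in one isolate.",
    "The {VAR} variant was observed in the screening panel.",
)
_MUTATION_COOC = "The {VAR} mutation had no measurable effect on the binding assay."
_MUTATION_COOC_DEGREE = "The {VAR} mutation slightly reduced the binding signal."
_MUTATION_PAIR_NOISE = (
    "The {VAR} mutation of {C} markedly reduced phosphorylation of {D}."
)
_NEGATION_PAIR = "The {VAR} mutation of {C} had no effect on binding to {D}."

_DEGREE_FILLERS = (
    "The inhibitor markedly reduced enzyme activity in this assay.",
    "Signal intensity was diminished after extensive washing.",
    "Pretreatment abolished the enzymatic response in control samples.",
    "Uptake was strongly impaired under hypoxic conditions.",
)

_NEUTRAL_FILLERS = (
    "Samples were collected and processed following standard protocols.",
    "Experiments were performed in triplicate with appropriate controls.",
)

_DISTRACTOR_PAIR = "{C} and {D} were detected in the same chromatographic fraction."
_SINGLE_GENE = "{E} transcript abundance was similar across conditions."


def _variant_token(rng: np.random.Generator) -> str:
    a, b = rng.choice(len(_AA1), size=2)
    return f"{_AA1[a]}{int(rng.integers(10, 999))}{_AA1[b]}"


class _DocBuilder:
    """Accumulates sentences and sentence-local annotations for one document."""

    def __init__(self, doc_id: str, title: str):
        self.doc_id = doc_id
        self.title = title
        self.sentences: list[str] = []
        self.annotations: list[tuple[int, int, int, str, str, str]] = []

    def add(self, sentence: str, marks: Iterable[tuple[str, str, str, str]] = ()) -> None:
        """Append a sentence; ``marks`` are (surface, type, norm_id, source)."""
        idx = len(self.sentences)
        self.sentences.append(sentence)
        cursor = 0
        for surface, etype, norm_id, source in marks:
            pos = sentence.find(surface, cursor)
            if pos == -1:
                pos = sentence.find(surface)
            self.annotations.append((idx, pos, pos + len(surface), etype, norm_id, source))
            cursor = pos + len(surface)

    def build(self) -> tuple[Document, list[EntityAnnotation]]:
        abstract = " ".join(self.sentences)
        doc = Document(self.doc_id, self.title, abstract).segment()
        offsets = []
        pos = len(self.title) + 1
        for sent in self.sentences:
            offsets.append(pos)
            pos += len(sent) + 1
        anns = []
        for idx, s, e, etype, norm_id, source in self.annotations:
            start = offsets[idx] + s
            end = offsets[idx] + e
            anns.append(
                EntityAnnotation(
                    self.doc_id, start, end, doc.text[start:end], etype, norm_id, source
                )
            )
        return doc, anns


def generate_synthetic_corpus(cfg: SynthConfig) -> CorpusBundle:
    """Generate a labelled, annotated corpus; fully reproducible per seed.

    The returned bundle carries documents, gene/mutation annotations, gold
    relations for relevant documents, binary labels and a per-document
    interaction-probability score emulating an interaction-detection tool.
    """
    if 2 * cfg.relations_per_relevant_doc + 2 > cfg.gene_inventory_size:
        raise ValueError(
            "gene inventory too small for the requested distinct pairs per document"
        )
    rng = np.random.default_rng(cfg.seed)
    gene_ids = [str(9_000_001 + i) for i in range(cfg.gene_inventory_size)]
    gene_names = {gid: f"PPG{i + 1}" for i, gid in enumerate(gene_ids)}

    bundle = CorpusBundle()
    n_relevant = int(round(cfg.n_docs * cfg.relevant_fraction))
    for i in range(cfg.n_docs):
        doc_id = f"D{i:05d}"
        relevant = i < n_relevant
        builder = _DocBuilder(
            doc_id, "Molecular characterisation of candidate protein partners."
        )
        mut_rate, mut_std = (
            (cfg.mutation_rate_relevant, cfg.mutation_std_relevant)
            if relevant
            else (cfg.mutation_rate_nonrelevant, cfg.mutation_std_nonrelevant)
        )
        int_rate, int_std = (
            (cfg.interaction_rate_relevant, cfg.interaction_std_relevant)
            if relevant
            else (cfg.interaction_rate_nonrelevant, cfg.interaction_std_nonrelevant)
        )
        interaction_budget = _draw_count(rng, int_rate, int_std, cfg.count_distribution)
        interaction_used = 0

        # planted relations
        chosen = rng.choice(
            len(gene_ids), size=2 * cfg.relations_per_relevant_doc + 2, replace=False
        )
        chosen_ids = [gene_ids[j] for j in chosen]
        if relevant:
            for r in range(cfg.relations_per_relevant_doc):
                id_a, id_b = chosen_ids[2 * r], chosen_ids[2 * r + 1]
                bundle.relations.add(
                    RelationAnnotation(doc_id, canonical_pair(id_a, id_b))
                )
                for k in range(cfg.relation_sentence_repeats):
                    template = _RELATION_TEMPLATES[k % len(_RELATION_TEMPLATES)]
                    var = _variant_token(rng)
                    sent = template.format(
                        A=gene_names[id_a], B=gene_names[id_b], VAR=var
                    )
                    builder.add(
                        sent,
                        [
                            (gene_names[id_a], "Gene", id_a, "gnorm"),
                            (gene_names[id_b], "Gene", id_b, "gnorm"),
                        ],
                    )
                    interaction_used += 2 if "interacts" in template else 1

        # tool-detectable mutations (the Table-style per-class count statistic)
        n_mut = _draw_count(rng, mut_rate, mut_std, cfg.count_distribution)
        for _ in range(n_mut):
            var = _variant_token(rng)
            if rng.random() < cfg.pair_noise:
                # near-miss: mutation modulates activity on a random gene pair
                j1, j2 = rng.choice(len(gene_ids), size=2, replace=False)
                id_c, id_d = gene_ids[int(j1)], gene_ids[int(j2)]
                sent = _MUTATION_PAIR_NOISE.format(
                    VAR=var, C=gene_names[id_c], D=gene_names[id_d]
                )
                builder.add(
                    sent,
                    [
                        (var, "Mutation", "", "pubtator"),
                        (gene_names[id_c], "Gene", id_c, "gnorm"),
                        (gene_names[id_d], "Gene", id_d, "gnorm"),
                    ],
                )
                interaction_used += 1  # "phosphorylation"
                continue
            if rng.random() < cfg.cooccurrence_noise:
                if rng.random() < cfg.degree_noise:
                    sent = _MUTATION_COOC_DEGREE.format(VAR=var)
                else:
                    sent = _MUTATION_COOC.format(VAR=var)
                interaction_used += 1  # "binding"
            else:
                sent = _MUTATION_PLAIN[int(rng.integers(len(_MUTATION_PLAIN)))].format(
                    VAR=var
                )
            builder.add(sent, [(var, "Mutation", "", "pubtator")])

        # non-relevant documents occasionally discuss a pair with no effect
        if not relevant and rng.random() < cfg.negation_noise:
            id_c, id_d = chosen_ids[-2], chosen_ids[-1]
            var = _variant_token(rng)
            sent = _NEGATION_PAIR.format(
                VAR=var, C=gene_names[id_c], D=gene_names[id_d]
            )
            builder.add(
                sent,
                [
                    (gene_names[id_c], "Gene", id_c, "gnorm"),
                    (gene_names[id_d], "Gene", id_d, "gnorm"),
                ],
            )
            interaction_used += 1  # "binding"

        # distractor pair mentioned in exactly one trigger-free sentence
        elif rng.random() < cfg.distractor_pair_prob:
            id_c, id_d = chosen_ids[-2], chosen_ids[-1]
            builder.add(
                _DISTRACTOR_PAIR.format(C=gene_names[id_c], D=gene_names[id_d]),
                [
                    (gene_names[id_c], "Gene", id_c, "gnorm"),
                    (gene_names[id_d], "Gene", id_d, "gnorm"),
                ],
            )

        # single-gene mention sentence
        if rng.random() < 0.5:
            id_e = chosen_ids[-1]
            builder.add(
                _SINGLE_GENE.format(E=gene_names[id_e]),
                [(gene_names[id_e], "Gene", id_e, "gnorm")],
            )

        # top up interaction-term mentions to the drawn budget
        for _ in range(max(0, interaction_budget - interaction_used)):
            builder.add(_INTERACTION_FILLERS[int(rng.integers(len(_INTERACTION_FILLERS)))])

        # degree and neutral fillers for both classes
        for _ in range(int(rng.poisson(0.8))):
            builder.add(_DEGREE_FILLERS[int(rng.integers(len(_DEGREE_FILLERS)))])
        builder.add(_NEUTRAL_FILLERS[int(rng.integers(len(_NEUTRAL_FILLERS)))])

        doc, annotations = builder.build()
        bundle.documents.append(doc)
        # annotation dropout thins gene annotations independently
        for ann in annotations:
            if ann.entity_type == "Gene" and rng.random() < cfg.annotation_dropout:
                continue
            bundle.annotations.add(ann)
        bundle.labels[doc_id] = int(relevant)
        score = rng.beta(5, 2) if relevant else rng.beta(2, 3)
        bundle.scores[doc_id] = float(min(max(score, 0.0), 1.0))

    bundle.validate()
    return bundle


def corpus_shift_variant(
    cfg: SynthConfig,
    shifted_rates: dict | None = None,
    test_n_docs: int | None = None,
) -> tuple[CorpusBundle, CorpusBundle]:
    """Paired train/test corpora with shifted non-relevant mutation rates.

    The test corpus is drawn from an independent seed with the mutation-count
    means replaced (defaults: the shifted test-distribution means), enabling
    reproduction of the false-positive inflation seen when a triage model
    trained under one mutation regime is applied under another.
    """
    shifted = dict(SHIFTED_MUTATION_RATES if shifted_rates is None else shifted_rates)
    test_cfg = replace(
        cfg,
        seed=(cfg.seed + 104_729) % (2 ** 31),
        n_docs=test_n_docs if test_n_docs is not None else cfg.n_docs,
        **shifted,
    )
    return generate_synthetic_corpus(cfg), generate_synthetic_corpus(test_cfg)


def tool_mutation_counts(bundle: CorpusBundle) -> dict[str, int]:
    """Per-document count of tool-annotated mutation mentions."""
    counts = {doc.doc_id: 0 for doc in bundle.documents}
    for ann in bundle.annotations:
        if ann.entity_type == "Mutation":
            counts[ann.doc_id] += 1
    return counts
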