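# Methods

This document describes the models implemented in `ppimine`, the assumptions
they make, the default parameters and the reasons for them, what the
synthetic corpus generator does and does not emulate, the numerical choices,
and known limitations.

## Problem setting

The target task is mining protein–protein interactions affected by genetic
mutations (PPIm) from PubMed-style records (title plus abstract). It has two
stages:

- **Triage**: a ranked binary classification of documents — does the document
  describe a mutation that changes a protein–protein interaction? The ranked
  view is evaluated by mean average precision (MAP) over all relevant
  documents; the binary view by precision, recall and F1.
- **Relation extraction**: for relevant documents, recover the unordered
  pairs of normalized gene identifiers whose interaction is affected,
  evaluated by micro-averaged precision/recall/F1 over (document, pair)
  instances.

## Corpus representation

Documents use a PubTator-style standoff format. Character offsets index the
concatenation `title + " " + abstract` (title alone when the abstract is
empty). Entity annotation lines carry span, surface, type and an optional
normalized identifier; the reader verifies the surface against the text and
fails hard with a line number on mismatch. Relation lines come in a
four-column dialect (`doc TAB type TAB id1 TAB id2`) and a three-column
dialect (`doc TAB id1 TAB id2`); both are canonicalized to sorted unordered
pairs, so evaluation is order-insensitive.

Sentence segmentation is a deterministic rule-based splitter: split on
`.!?` followed by whitespace and an upper-case or digit start, with a guard
list of common abbreviations (`Fig.`, `e.g.`, `p.`, `c.` …) so mutation
nomenclature such as `p.R97A` survives intact. It is intentionally simple
and auditable rather than learned.

## Term matching

A self-contained Porter stemmer drives all trigger matching. Four stemmed
term lists are packaged (`src/ppimine/data/term_lists.txt`): 30 interaction
terms, 23 degree terms, 15 strong mutation terms and 9 weak mutation terms.
Matching stems every token of the document and compares against the stemmed
lists; a *weak* mutation term (e.g. "change", "exchange") only counts when an
amino-acid mention occurs in the same sentence (or anywhere in the document
with `weak_scope="document"`), because such words are pervasive in prose
that has nothing to do with mutations. Amino-acid detection accepts the 20
full names case-insensitively and the 20 three-letter codes only in Title or
UPPER case with word boundaries, so English words like "his" or "met" never
match.

## Annotation ensemble

Gene annotations from three sources (a task-specific recognizer, a gene
normalizer, a general-purpose tagger) are merged at fixpoint: overlapping
mentions collapse to their minimal superstring span, and the identifier is
chosen by source priority (task > normalizer > general tagger) with the rule
that an absent identifier never wins over a present one. Sweeps are ordered
by (start, −length) so the merge is deterministic and independent of input
order. `max_achievable_recall` reports the fraction of gold pairs whose two
identifiers both survive in the annotation set — an upper bound on any
downstream extractor's recall.

## Triage features and models

Each document maps to 27 features F1–F27 grouped into 11 sets S1–S11:
mutation mention and sentence counts (tool-based and term-based), interaction
and degree trigger counts, gene mention/distinct-id counts, sentence-level
gene-pair co-mentions (tool-based pairs require two distinct identifiers in
one sentence), mutation–interaction and mutation–gene-pair sentence
conjunctions, an upstream relevance score when available, and an impact
score. The impact score is 0 when either corpus-wide total is 0 and
otherwise `α·mut/max_mut + β·int/max_int` with α = β = 0.5 — both signals
weighted equally by default because neither is privileged a priori.
`FeatureVector.validate()` enforces the internal consistency constraints
(sentence counts never exceed mention counts, conjunction counts never
exceed their conjuncts, ratios stay in [0, 1]).

Models: `boosted_lr` (AdaBoost with 50 logistic-regression base learners —
50 rounds is a conventional boosting budget that converges on corpora of a
few thousand documents without overfitting the folds), `svm` (linear SVM),
`random_forest`, and `baseline_lr` over TF-IDF bag-of-words. The TF-IDF
analyzer casefolds, drops stopwords and digit tokens, and stems; it is
always fitted inside the training fold only. Cross-validation is stratified
10-fold by default (the conventional protocol for corpora of this size);
fold summaries report the mean and population standard deviation (ddof = 0)
across folds. Ranking ties are broken by document identifier so rankings
are total and reproducible.

## Relation extraction

**Co-occurrence rules.** H1: never emit self-pairs (identical identifiers).
H2: emit a pair when it co-occurs in at least N sentences; N = 3 by default,
a strict-enough threshold to suppress incidental co-mention while catching
pairs that an abstract restates. H3 (the "default rule", on by default):
when a sentence contains exactly one pair and an interaction trigger (stem
"interact"), emit that pair even below the threshold. With H3 disabled the
extracted sets are nested and recall is non-increasing in N; H3 breaks
strict nesting by design because it is threshold-independent.

**Supervised graphs.** Candidate pairs are enumerated from distinct-id gene
mentions within a sentence window (`max_sentence_distance = 3` by default —
cross-sentence pairs farther apart are rarely asserted and explode the
candidate space; `None` lifts the cap). Each candidate carries a sentence
graph: a dependency graph when CoNLL-U parses are supplied, otherwise a
token-chain graph with "next" edges; cross-sentence candidates join the two
graphs with a root-to-root `SENT_LINK` edge. The two argument mentions are
masked as `Protein1`/`Protein2` in document order, and bystander entities as
`Protein_Other`/`Mutation_Other`, so the learner sees structure rather than
memorizing gene names. Features are lowercased node labels, labelled edges,
the shortest `protein1 → … → protein2` label path and its length, hashed
into 2^16 dimensions (a fixed-size space that keeps training linear-time)
and fed to a hinge-loss linear model with class weighting to counter the
negative-candidate imbalance.

## Synthetic corpus generator

The generator produces corpora whose *statistics* mimic a PPIm triage
collection, so pipeline claims can be tested against a known ground truth.

What it emulates:

- Class-conditional counts of mutation and interaction trigger mentions
  drawn from Poisson distributions with distinct means for relevant and
  non-relevant documents (defaults: mutation 1.6744 vs 0.7046; interaction
  15.6217 vs 14.3366), plus a shifted-rate variant (2.6520 vs 2.2517) for
  distribution-shift experiments — means chosen so the two classes overlap
  substantially, as real corpora do.
- Planted gene-pair relations restated in `relation_sentence_repeats = 3`
  sentences, so a co-occurrence threshold of N = 3 is exactly attainable.
- Noise processes: co-occurrence noise (mutation sentences that also mention
  an unrelated gene), degree-term filler, negation sentences, distractor
  gene pairs that co-occur once but are not related, and "pair noise"
  (probability 0.08 that a mutation sentence names a fresh random gene pair
  with an interaction word) — the last makes false-positive rates scale with
  the mutation rate and prevents any single feature from separating the
  classes perfectly.
- Annotation dropout that thins gene annotations independently with
  probability d, under which the achievable-recall bound has the analytic
  expectation `(1 − d^m)²` with m the number of restatement sentences.
- Shared template vocabulary across classes, so a lexical bag-of-words
  baseline cannot win on vocabulary identity alone.

What it does not emulate: real English syntax or discourse, gene-name
ambiguity and normalization errors, tagger-specific error profiles,
document-length variation beyond sentence counts, and inter-annotator
disagreement. Conclusions drawn on synthetic corpora are statements about
the pipeline's mechanics, not about performance on real literature.

## Numerical choices

- All randomness flows through `numpy.random.default_rng` seeded explicitly;
  derived seeds stay below 2^31. Same seed ⇒ byte-identical corpora and
  identical model outputs.
- Cross-validation dispersion uses the population standard deviation
  (ddof = 0) because the folds are the entire population of interest, not a
  sample.
- The two-sample z-test uses sample variances (ddof = 1), requires n ≥ 30
  per side (below that it raises and recommends a t-test), and returns
  (0.0, 1.0) when the pooled standard error is zero.
- Metric implementations are closed-form over sets and sums; tests compare
  them against brute-force re-implementations at 1e-12.

## Limitations

- The chain-graph fallback loses syntactic structure; supervised extraction
  is strongest when CoNLL-U parses are provided.
- The sentence splitter and stemmer are rule-based approximations; unusual
  abbreviations or morphology can mis-segment or mis-stem.
- The co-occurrence default rule (H3) trades precision for recall and is
  tied to a single trigger stem.
- Evaluation assumes gold pairs use the same identifier space as the
  annotations; no identifier mapping is attempted.
- Synthetic results upper-bound real-world difficulty: template text is far
  easier than natural abstracts for both the engineered features and the
  lexical baseline.
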