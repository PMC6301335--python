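"""Ranked binary classifiers for PPIm document triage.

Four algorithms are exposed: a tf-idf logistic-regression baseline, adaptive
boosting over logistic-regression base learners ("boosted LR", 50 rounds by
default), a linear SVM ranked by decision scores, and a random forest.  All
are evaluated with stratified 10-fold cross-validation; per-fold metrics are
summarized as mean plus the population standard deviation over folds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.svm import LinearSVC

from .evaluation import Metrics, triage_metrics
from .triage_features import FEATURE_NAMES, FEATURE_SETS, build_tfidf

logger = logging.getLogger(__name__)

ALGORITHMS = ("boosted_lr", "svm", "random_forest", "baseline_lr")


@dataclass(frozen=True)
class CVConfig:
    folds: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def _make_estimator(algorithm: str, seed: int, boosting_rounds: int = 50):
    if algorithm == "boosted_lr":
        return AdaBoostClassifier(
            estimator=LogisticRegression(max_iter=1000),
            n_estimators=boosting_rounds,
            random_state=seed,
        )
    if algorithm == "svm":
        return LinearSVC(random_state=seed)
    if algorithm == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if algorithm == "baseline_lr":
        return LogisticRegression(max_iter=1000, random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class TriageModel:
    algorithm: str
    estimator: object
    feature_names: tuple[str, ...]

    def _check_schema(self, X) -> None:
        n = X.shape[1]
        if n != len(self.feature_names):
            raise ValueError(
                f"schema mismatch: model expects {len(self.feature_names)} features "
                f"{list(self.feature_names)[:5]}..., got {n} columns"
            )

    def scores(self, X) -> np.ndarray:
        """Relevance score per document, used for ranking."""
        self._check_schema(X)
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return est.predict_proba(X)[:, 1]
        return est.decision_function(X)

    def predict(self, X) -> np.ndarray:
        self._check_schema(X)
        return self.estimator.predict(X)


def train_triage(
    X,
    y: Sequence[int],
    algorithm: str = "boosted_lr",
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
    boosting_rounds: int = 50,
) -> TriageModel:
    """Fit a triage classifier; deterministic given the seed."""
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X rows and y length differ")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_estimator(algorithm, seed, boosting_rounds)
    est.fit(X, y)
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    return TriageModel(algorithm, est, tuple(feature_names))


def rank_documents(
    model: TriageModel, X, doc_ids: Sequence[str]
) -> list[tuple[str, float, int]]:
    """Rank documents by relevance score, ties broken by doc_id."""
    scores = model.scores(X)
    preds = model.predict(X)
    rows = sorted(
        zip(doc_ids, scores, preds), key=lambda t: (-t[1], t[0])
    )
    return [(d, float(s), int(p)) for d, s, p in rows]


def select_feature_columns(feature_sets: Sequence[str]) -> list[str]:
    """Expand cumulative S-group names into F-feature column names."""
    columns: list[str] = []
    for name in feature_sets:
        if name == "tfidf":
            continue
        if name not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {name!r}")
        columns.extend(FEATURE_SETS[name])
    return columns


def _assemble(
    features: pd.DataFrame | None,
    columns: list[str],
    tfidf_block,
):
    parts = []
    if columns:
        missing = [c for c in columns if c not in features.columns]
        if missing:
            raise ValueError(f"feature matrix is missing columns {missing}")
        parts.append(sparse.csr_matrix(features[columns].to_numpy(dtype=float)))
    if tfidf_block is not None:
        parts.append(sparse.csr_matrix(tfidf_block))
    if not parts:
        raise ValueError("no features selected")
    return parts[0] if len(parts) == 1 else sparse.hstack(parts, format="csr")


@dataclass
class CVResult:
    per_fold: list[Metrics]
    algorithm: str
    feature_sets: tuple[str, ...]
    fold_assignment: dict[str, int] = field(default_factory=dict)

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean and population standard deviation of each metric over folds."""
        out = {}
        for name in ("ranked_precision", "precision", "recall", "f1"):
            vals = np.array([getattr(m, name) for m in self.per_fold])
            out[name] = (float(vals.mean()), float(vals.std(ddof=0)))
        return out

    @property
    def mean_f1(self) -> float:
        return self.summary()["f1"][0]


def cross_validate(
    features: pd.DataFrame,
    labels: Mapping[str, int],
    cfg: CVConfig = CVConfig(),
    algorithm: str = "boosted_lr",
    feature_sets: Sequence[str] = ("S1", "S2", "S3", "S4", "S5", "S6", "S7", "S8", "S9", "S10", "S11"),
    texts: Mapping[str, str] | None = None,
    boosting_rounds: int = 50,
) -> CVResult:
    """Stratified k-fold cross-validation of a triage model.

    ``feature_sets`` selects cumulative S-groups and/or ``"tfidf"``; when
    tf-idf is included, the vocabulary and idf statistics are fitted on each
    training fold only.  Folds are disjoint and cover the corpus; each
    document is tested exactly once.
    """
    doc_ids = list(features.index)
    y = np.array([labels[d] for d in doc_ids])
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("cross-validation needs both classes")
    if cfg.stratified and counts.min() < cfg.folds:
        raise ValueError(
            f"too few examples in the smallest class ({counts.min()}) for "
            f"{cfg.folds} stratified folds"
        )
    use_tfidf = "tfidf" in feature_sets
    if use_tfidf and texts is None:
        raise ValueError("tfidf feature set requires document texts")
    columns = select_feature_columns(feature_sets)

    splitter = (
        StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
        if cfg.stratified
        else KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    )
    per_fold: list[Metrics] = []
    fold_assignment: dict[str, int] = {}
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        for i in test_idx:
            fold_assignment[doc_ids[i]] = fold
        train_tfidf = test_tfidf = None
        if use_tfidf:
            train_texts = [texts[doc_ids[i]] for i in train_idx]
            train_tfidf, vectorizer = build_tfidf(train_texts)
            test_tfidf = vectorizer.transform([texts[doc_ids[i]] for i in test_idx])
        X_train = _assemble(features.iloc[train_idx], columns, train_tfidf)
        X_test = _assemble(features.iloc[test_idx], columns, test_tfidf)
        model = train_triage(
            X_train, y[train_idx], algorithm, cfg.seed, boosting_rounds=boosting_rounds
        )
        ranked = rank_documents(model, X_test, [doc_ids[i] for i in test_idx])
        per_fold.append(
            triage_metrics([(d, p) for d, _s, p in ranked], labels)
        )
    return CVResult(per_fold, algorithm, tuple(feature_sets), fold_assignment)
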