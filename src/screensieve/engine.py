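"""Text featurization, classifier training and certainty-based ranking.

This is the model core shared by the noisy-label filter and the screening
simulator: records are embedded as L2-normalized unigram tf-idf rows, one of
four classifiers is fitted on the labelled records, and the unlabeled pool is
ranked by predicted relevance (the certainty / maximum query strategy).

Everything here is a pure, seeded function of its inputs: the same corpus,
labels and :class:`ModelSpec` always produce the same ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import scipy.sparse as sp
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import MultinomialNB
from sklearn.svm import LinearSVC

from .records import Corpus, Label

CLASSIFIER_NAMES = ("logistic_regression", "naive_bayes", "random_forest", "svm")

#: short aliases accepted on the command line
CLASSIFIER_ALIASES = {
    "lr": "logistic_regression",
    "nb": "naive_bayes",
    "rf": "random_forest",
    "svm": "svm",
}


@dataclass(frozen=True)
class ModelSpec:
    """Choice of classifier, its hyperparameters, and the training seed."""

    classifier_name: str = "naive_bayes"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        name = CLASSIFIER_ALIASES.get(self.classifier_name, self.classifier_name)
        if name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.classifier_name!r}; "
                f"choose one of {CLASSIFIER_NAMES}"
            )
        object.__setattr__(self, "classifier_name", name)
        object.__setattr__(self, "hyperparameters", dict(self.hyperparameters))


class FeatureMatrix:
    """Sparse tf-idf matrix with a row ↔ record_id map.

    Rows are L2-normalized (norm 1 for any record with at least one token,
    norm 0 for empty text); weights are non-negative; the vocabulary is in
    deterministic lexicographic order.
    """

    def __init__(self, record_ids: tuple[str, ...], matrix: sp.csr_matrix,
                 vocabulary: tuple[str, ...]):
        self.record_ids = record_ids
        self.matrix = matrix
        self.vocabulary = vocabulary
        self._row: dict[str, int] = {rid: i for i, rid in enumerate(record_ids)}

    def rows_for(self, record_ids) -> sp.csr_matrix:
        idx = [self._row[rid] for rid in record_ids]
        return self.matrix[idx]


def build_features(corpus: Corpus) -> FeatureMatrix:
    """Unigram tf-idf features over title + abstract.

    Text is casefolded and tokenized on non-alphanumeric boundaries; idf is
    smoothed (``ln((1+n)/(1+df)) + 1``); rows are L2-normalized.  No stop-word
    removal, no vocabulary cap.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    texts = [r.text for r in corpus]
    vectorizer = TfidfVectorizer(
        preprocessor=str.casefold,
        token_pattern=r"[a-z0-9]+",
        lowercase=False,
        norm="l2",
        smooth_idf=True,
        sublinear_tf=False,
    )
    try:
        matrix = vectorizer.fit_transform(texts)
    except ValueError as exc:  # all texts empty → no vocabulary
        if "empty vocabulary" in str(exc):
            import logging

            logging.getLogger(__name__).warning(
                "all record texts are empty; features are zero-dimensional"
            )
            matrix = sp.csr_matrix((len(texts), 0))
            return FeatureMatrix(corpus.record_ids, matrix, ())
        raise
    vocab = tuple(sorted(vectorizer.vocabulary_, key=vectorizer.vocabulary_.get))
    return FeatureMatrix(corpus.record_ids, matrix.tocsr(), vocab)


def _make_classifier(spec: ModelSpec):
    params = dict(spec.hyperparameters)
    if spec.classifier_name == "naive_bayes":
        params.setdefault("alpha", 1.0)
        return MultinomialNB(**params)
    if spec.classifier_name == "logistic_regression":
        params.setdefault("C", 1.0)
        params.setdefault("solver", "lbfgs")
        params.setdefault("max_iter", 1000)
        return LogisticRegression(**params)
    if spec.classifier_name == "svm":
        params.setdefault("C", 1.0)
        params.setdefault("dual", True)
        params.setdefault("max_iter", 5000)
        return LinearSVC(random_state=spec.seed, **params)
    if spec.classifier_name == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestClassifier(random_state=spec.seed, **params)
    raise AssertionError(spec.classifier_name)


class FittedPredictor:
    """A trained classifier exposing a monotone relevance score.

    Probabilistic classifiers score with the relevant-class probability;
    the linear SVM with its signed decision margin.  Both are monotone in
    predicted relevance, which is all ranking needs.
    """

    def __init__(self, clf, probabilistic: bool):
        self._clf = clf
        self._probabilistic = probabilistic

    def score(self, X: sp.csr_matrix) -> np.ndarray:
        if self._probabilistic:
            idx = int(np.flatnonzero(self._clf.classes_ == 1)[0])
            return self._clf.predict_proba(X)[:, idx]
        return np.asarray(self._clf.decision_function(X), dtype=float)


def train(
    spec: ModelSpec,
    features: FeatureMatrix,
    labels: Mapping[str, Label],
) -> FittedPredictor:
    """Fit the classifier on the labelled records.

    ``labels`` maps record_id → RELEVANT/IRRELEVANT.  Class imbalance is
    handled by inverse-frequency sample weights (each class contributes equal
    total weight), uniformly across all four classifiers.
    """
    ids = list(labels)
    y = np.array([1 if labels[rid] is Label.RELEVANT else 0 for rid in ids])
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("training set has no RELEVANT records")
    if n_pos == len(y):
        raise ValueError("training set has no IRRELEVANT records")
    X = features.rows_for(ids)
    # inverse class frequency, normalized so total weight = n
    w = np.where(y == 1, len(y) / (2.0 * n_pos), len(y) / (2.0 * (len(y) - n_pos)))
    clf = _make_classifier(spec)
    clf.fit(X, y, sample_weight=w)
    return FittedPredictor(clf, probabilistic=spec.classifier_name != "svm")


@dataclass(frozen=True)
class RankedList:
    """Record ids in descending predicted-relevance order; total order.

    Ties broken by ascending record_id, so the order is unique.
    """

    order: tuple[str, ...]
    scores: Mapping[str, float]

    @property
    def top(self) -> str:
        return self.order[0]


def rank_unlabeled(
    predictor: FittedPredictor,
    features: FeatureMatrix,
    unlabeled: set[str] | frozenset[str] | tuple[str, ...],
) -> RankedList:
    """Rank the unlabeled records by predicted relevance (certainty strategy)."""
    ids = sorted(unlabeled)
    if not ids:
        raise ValueError("unlabeled set is empty")
    scores = predictor.score(features.rows_for(ids))
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return RankedList(
        order=tuple(ids[i] for i in order),
        scores={ids[i]: float(scores[i]) for i in range(len(ids))},
    )
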