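"""Rank fusion and second-stage reranking.

**Reciprocal rank fusion (RRF).**  Given ranked lists r_1..r_n for one
topic, each document's fused score is::

    score(d) = sum over lists containing d of  1 / (k + rank_i(d))

with the threshold k defaulting to 60.  RRF needs only ranks, which makes
it robust to incomparable score scales and is the glue between every
stage of the pipeline.

**Reranker contract.**  A second-stage scorer is any deterministic
callable ``(topic, document) -> float`` over a documented finite range.
Heavy neural relevance classifiers plug in through this contract; the
shipped scorers are deterministic lexical-overlap mocks (fraction of a
topic field's terms found in title + abstract), registered under
``overlap-query`` / ``overlap-question`` / ``overlap-narrative``.

**Feature-level fusion.**  For learning-to-rank, the per-model similarity
scores of the same (topic, document) pair are assembled into a feature
table (documents missing from a model's list are imputed below that
model's per-topic minimum and flagged), then a pointwise L2-regularized
logistic regression is fitted on binarized judgments (grades 1 and 2 are
both "relevant") and its probabilities become the fused ranking.
Training is a deterministic full-batch optimization from zero
initialization on internally z-scored features.

A pairwise (LambdaMART-style) model is accommodated by the
``PAIRWISE_REGISTRY`` contract but not shipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .corpus_io import DocumentRecord, IntegrityError, JudgmentSet, RankedList, RunEntry
from .corpus_io import TopicRecord
from .text_pipeline import normalize

__all__ = [
    "RRFParams",
    "rrf_fuse",
    "RerankScorer",
    "lexical_overlap_scorer",
    "SCORER_REGISTRY",
    "PAIRWISE_REGISTRY",
    "rerank_topk",
    "FeatureTable",
    "assemble_features",
    "LogisticModel",
    "fit_logistic",
    "score_logistic",
    "TrainingError",
]

#: offset subtracted from a model's per-topic minimum when imputing the
#: feature of a document that model never retrieved
IMPUTE_OFFSET = 1.0


class TrainingError(ValueError):
    """The learning-to-rank training set is unusable."""


@dataclass(frozen=True)
class RRFParams:
    """k: positive rank-damping threshold (default 60)."""

    k: float = 60.0

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"RRF k must be positive, got {self.k}")


def rrf_fuse(lists: Sequence[RankedList], params: RRFParams = RRFParams(),
             tag: str = "rrf", top_k: int | None = None) -> RankedList:
    """Fuse ranked lists for one topic by reciprocal rank.

    Documents absent from a list contribute nothing from it.  Output
    sorted score descending, doc_id ascending on ties.
    """
    if not lists:
        raise IntegrityError("rrf_fuse needs at least one list")
    topic = lists[0].topic
    if any(l.topic != topic for l in lists):
        raise IntegrityError("rrf_fuse received lists for different topics")
    ranks: dict[str, list[int]] = {}
    for lst in lists:
        for e in lst.entries:
            ranks.setdefault(e.doc_id, []).append(e.rank)
    # summing each document's contributions in sorted rank order makes the
    # fused scores bit-for-bit independent of the order of the input lists
    scores = {d: sum(1.0 / (params.k + r) for r in sorted(rs))
              for d, rs in ranks.items()}
    return RankedList.from_scores(topic, scores, tag=tag, top_k=top_k)


#: the reranker contract: deterministic, total, finite range
RerankScorer = Callable[[TopicRecord, DocumentRecord], float]


def lexical_overlap_scorer(source: str = "question") -> RerankScorer:
    """Deterministic mock reranker: fraction of the topic field's
    normalized terms present in the document's title + abstract.

    Range [0, 1]; stands in for a trained relevance classifier wherever
    one would plug into the reranking stage.
    """
    if source not in ("query", "question", "narrative"):
        raise ValueError(f"unknown topic field {source!r}")

    def score(topic: TopicRecord, doc: DocumentRecord) -> float:
        terms = set(normalize(getattr(topic, source)))
        if not terms:
            return 0.0
        doc_terms = set(normalize(doc.title + " " + doc.abstract))
        return len(terms & doc_terms) / len(terms)

    score.__name__ = f"overlap_{source}"
    return score


#: scorer plug-ins discoverable by name from the pipeline config
SCORER_REGISTRY: dict[str, RerankScorer] = {
    "overlap-query": lexical_overlap_scorer("query"),
    "overlap-question": lexical_overlap_scorer("question"),
    "overlap-narrative": lexical_overlap_scorer("narrative"),
}

#: slot for pairwise list rerankers (LambdaMART-style plug-ins); empty by
#: default — recipes requiring one fail fast with a configuration error
PAIRWISE_REGISTRY: dict[str, Callable] = {}


def rerank_topk(first_stage: RankedList, scorer: RerankScorer,
                topic: TopicRecord, corpus: Mapping[str, DocumentRecord],
                k: int = 5000, tag: str | None = None) -> RankedList:
    """Rescore the top-k of a first-stage list with a second-stage scorer.

    Entries beyond k are dropped; output scores are the scorer's, sorted
    with the usual doc_id tie rule.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    head = first_stage.entries[:k]
    scores: dict[str, float] = {}
    for e in head:
        doc = corpus.get(e.doc_id)
        if doc is None:
            raise IntegrityError(f"doc {e.doc_id!r} missing from corpus lookup")
        scores[e.doc_id] = scorer(topic, doc)
    return RankedList.from_scores(first_stage.topic, scores,
                                  tag=tag or getattr(scorer, "__name__", "rerank"))


@dataclass
class FeatureTable:
    """Per (topic, doc) feature vectors of model similarity scores.

    ``imputed[i][j]`` flags that feature j of row i was filled in because
    model j never retrieved that document for that topic.  ``labels`` is
    present only when judgments were supplied: 1 for grades >= 1, 0 for
    grade 0, None for unjudged rows (excluded from training).
    """

    feature_names: tuple[str, ...]
    keys: list[tuple[int, str]]
    matrix: np.ndarray
    imputed: np.ndarray
    labels: list[int | None] | None = None

    def training_rows(self) -> tuple[np.ndarray, np.ndarray]:
        if self.labels is None:
            raise TrainingError("feature table carries no labels")
        idx = [i for i, y in enumerate(self.labels) if y is not None]
        if not idx:
            raise TrainingError("no judged rows available for training")
        return self.matrix[idx], np.array([self.labels[i] for i in idx], dtype=float)


def assemble_features(runs: Mapping[str, Sequence[RankedList]],
                      qrels: JudgmentSet | None = None) -> FeatureTable:
    """Build the feature table from several models' runs.

    ``runs`` maps model name -> one RankedList per topic.  The row set is,
    per topic, the union of documents over all models; a document missing
    from some model's list gets that model's per-topic minimum score minus
    a fixed offset, flagged in ``imputed``.
    """
    if not runs:
        raise IntegrityError("assemble_features needs at least one run")
    names = tuple(sorted(runs))
    by_model: dict[str, dict[int, RankedList]] = {}
    topics: set[int] = set()
    for name in names:
        by_model[name] = {}
        for lst in runs[name]:
            if lst.topic in by_model[name]:
                raise IntegrityError(
                    f"model {name!r} has two lists for topic {lst.topic}")
            by_model[name][lst.topic] = lst
            topics.add(lst.topic)

    keys: list[tuple[int, str]] = []
    for topic in sorted(topics):
        union: dict[str, None] = {}
        for name in names:
            lst = by_model[name].get(topic)
            if lst is not None:
                for e in lst.entries:
                    union.setdefault(e.doc_id)
        keys.extend((topic, d) for d in sorted(union))
    if not keys:
        raise IntegrityError("union of run documents is empty")

    matrix = np.zeros((len(keys), len(names)))
    imputed = np.zeros((len(keys), len(names)), dtype=bool)
    row_of = {key: i for i, key in enumerate(keys)}
    for j, name in enumerate(names):
        for topic in sorted(topics):
            lst = by_model[name].get(topic)
            entries = lst.entries if lst is not None else []
            present = {e.doc_id: e.score for e in entries}
            floor = (min(present.values()) if present else 0.0) - IMPUTE_OFFSET
            for (t, d), i in row_of.items():
                if t != topic:
                    continue
                if d in present:
                    matrix[i, j] = present[d]
                else:
                    matrix[i, j] = floor
                    imputed[i, j] = True

    labels = None
    if qrels is not None:
        labels = []
        for topic, doc_id in keys:
            grade = qrels.grade(topic, doc_id)
            labels.append(None if grade is None else int(grade >= 1))
    return FeatureTable(feature_names=names, keys=keys, matrix=matrix,
                        imputed=imputed, labels=labels)


@dataclass
class LogisticModel:
    """Fitted pointwise fusion model in standardized feature space."""

    feature_names: tuple[str, ...]
    weights: np.ndarray
    bias: float
    feature_mean: np.ndarray
    feature_std: np.ndarray
    l2: float
    n_iter: int
    converged: bool

    def decision_function(self, matrix: np.ndarray) -> np.ndarray:
        z = (matrix - self.feature_mean) / self.feature_std
        return z @ self.weights + self.bias

    def predict_proba(self, matrix: np.ndarray) -> np.ndarray:
        return expit(self.decision_function(matrix))

    def penalized_nll(self, matrix: np.ndarray, labels: np.ndarray) -> float:
        """Sum of logistic losses + (l2/2)||w||^2 on standardized features."""
        margin = self.decision_function(matrix) * (2 * labels - 1)
        return float(np.logaddexp(0.0, -margin).sum()
                     + 0.5 * self.l2 * self.weights @ self.weights)


def fit_logistic(table: FeatureTable, l2: float = 1.0, max_iter: int = 500,
                 tol: float = 1e-8) -> LogisticModel:
    """Fit the L2-penalized logistic fusion model.

    Deterministic full-batch optimization (quasi-Newton) of the penalized
    negative log-likelihood from zero initialization; the bias is not
    penalized.  Features are z-scored internally over the training rows
    (constant features get unit scale).
    """
    if l2 < 0:
        raise ValueError(f"l2 must be nonnegative, got {l2}")
    x, y = table.training_rows()
    classes = set(y.tolist())
    if classes != {0.0, 1.0}:
        raise TrainingError(
            "training needs at least one positive and one negative label")
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0.0] = 1.0
    z = (x - mean) / std
    sign = 2 * y - 1  # +-1 targets

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w, b = theta[:-1], theta[-1]
        margin = (z @ w + b) * sign
        loss = np.logaddexp(0.0, -margin).sum() + 0.5 * l2 * w @ w
        p = expit(-margin)  # d loss / d margin = -p
        coef = -p * sign
        grad_w = z.T @ coef + l2 * w
        grad_b = coef.sum()
        return float(loss), np.concatenate([grad_w, [grad_b]])

    result = minimize(objective, np.zeros(z.shape[1] + 1), jac=True,
                      method="L-BFGS-B",
                      options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10})
    return LogisticModel(
        feature_names=table.feature_names,
        weights=result.x[:-1],
        bias=float(result.x[-1]),
        feature_mean=mean,
        feature_std=std,
        l2=l2,
        n_iter=int(result.nit),
        converged=bool(result.success),
    )


def score_logistic(model: LogisticModel, table: FeatureTable,
                   tag: str = "logistic", top_k: int | None = None
                   ) -> list[RankedList]:
    """Score every row of the table; one RankedList per topic, ranked by
    the model probability."""
    if table.feature_names != model.feature_names:
        raise IntegrityError("feature table does not match the fitted model")
    probs = model.predict_proba(table.matrix)
    per_topic: dict[int, dict[str, float]] = {}
    for (topic, doc_id), p in zip(table.keys, probs):
        per_topic.setdefault(topic, {})[doc_id] = float(p)
    return [RankedList.from_scores(topic, scores, tag=tag, top_k=top_k)
            for topic, scores in sorted(per_topic.items())]
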