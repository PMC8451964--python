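"""Field-aware inverted index, combinatorial querying and date filtering.

Two index flavours mirror the two views of a literature corpus:

* **metadata** index: title + abstract;
* **fulltext** index: title + (abstract followed by full text).

Each index stores three searchable sections per document — ``title``,
``abstract`` (which for the fulltext index is abstract + full text) and
``whole`` (title then abstract section, concatenated) — with the per-field
statistics every weighting model needs: term frequencies f(t,d), document
lengths |d|, average length avg_l, document count |D|, document
frequencies n_t and collection frequencies cf.

The query strategy is combinatorial: for a three-field topic, each of
{query, question, narrative} is run against each of {title, abstract},
and the concatenation of all three fields against the whole document —
seven queries per topic whose scores are summed unweighted.

A date cutoff (default semantics: keep documents published on or after
the cutoff day, i.e. a half-open filter) removes pre-outbreak noise;
documents with no parseable date are retained by default so that corpus
defects stay visible.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import DocumentRecord, JudgmentSet, RankedList, TopicRecord
from .text_pipeline import SynonymTable, expand, normalize
from .weighting import MODEL_HANDLES, term_weight

__all__ = [
    "ConfigurationError",
    "IndexConfig",
    "QuerySpec",
    "FieldStats",
    "InvertedIndex",
    "build_index",
    "make_query_plan",
    "search",
    "fit_params",
    "save_index",
    "load_index",
    "DEFAULT_CUTOFF",
]

#: first public reports of the outbreak: keep publications from this day on
DEFAULT_CUTOFF = datetime.date(2019, 12, 1)

INDEX_FORMAT = "pubrank-index"
INDEX_VERSION = 1


class ConfigurationError(ValueError):
    """An operation was configured inconsistently."""


@dataclass(frozen=True)
class IndexConfig:
    """kind: "metadata" or "fulltext"; cutoff: optional search-time date
    filter; keep_undated: whether documents without a date survive it."""

    kind: str = "metadata"
    cutoff: datetime.date | None = None
    keep_undated: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("metadata", "fulltext"):
            raise ConfigurationError(f"unknown index kind {self.kind!r}")


@dataclass(frozen=True)
class QuerySpec:
    """One of a topic's combinatorial queries: a topic source field run
    against one document section."""

    topic: int
    source: str      # query | question | narrative | all
    target: str      # title | abstract | whole
    terms: tuple[str, ...]


@dataclass
class FieldStats:
    """Postings and statistics for one searchable section."""

    postings: dict[str, dict[str, int]] = field(default_factory=dict)
    doc_len: dict[str, int] = field(default_factory=dict)

    @property
    def n_docs(self) -> int:
        return len(self.doc_len)

    @property
    def total_terms(self) -> int:
        return sum(self.doc_len.values())

    @property
    def avg_len(self) -> float:
        return self.total_terms / self.n_docs if self.n_docs else 0.0

    def doc_freq(self, term: str) -> int:
        return len(self.postings.get(term, ()))

    def coll_freq(self, term: str) -> int:
        return sum(self.postings.get(term, {}).values())

    def tf(self, term: str, doc_id: str) -> int:
        return self.postings.get(term, {}).get(doc_id, 0)

    def add_doc(self, doc_id: str, terms: Sequence[str]) -> None:
        self.doc_len[doc_id] = len(terms)
        for t in terms:
            self.postings.setdefault(t, {})
            self.postings[t][doc_id] = self.postings[t].get(doc_id, 0) + 1


class InvertedIndex:
    """Per-section postings plus document dates for one index flavour."""

    SECTIONS = ("title", "abstract", "whole")

    def __init__(self, kind: str):
        self.kind = kind
        self.fields: dict[str, FieldStats] = {s: FieldStats() for s in self.SECTIONS}
        self.dates: dict[str, datetime.date | None] = {}

    @property
    def doc_ids(self) -> list[str]:
        return list(self.fields["whole"].doc_len)

    @property
    def n_docs(self) -> int:
        return len(self.dates)

    def add_document(self, doc: DocumentRecord) -> None:
        title_terms = normalize(doc.title)
        body_text = doc.abstract
        if self.kind == "fulltext" and doc.full_text:
            body_text = doc.abstract + " " + doc.full_text
        body_terms = normalize(body_text)
        self.fields["title"].add_doc(doc.doc_id, title_terms)
        self.fields["abstract"].add_doc(doc.doc_id, body_terms)
        self.fields["whole"].add_doc(doc.doc_id, list(title_terms) + list(body_terms))
        self.dates[doc.doc_id] = doc.publish_date


def build_index(corpus: Sequence[DocumentRecord],
                config: IndexConfig = IndexConfig()) -> InvertedIndex:
    """Build an inverted index over the corpus.

    The metadata index covers title + abstract; the fulltext index covers
    title + abstract + full text.  The "whole" pseudo-section is the
    concatenation title -> abstract (-> full text).
    """
    if not corpus:
        raise ConfigurationError("cannot index an empty corpus")
    index = InvertedIndex(config.kind)
    seen: set[str] = set()
    for doc in corpus:
        if doc.doc_id in seen:
            raise ConfigurationError(f"duplicate doc_id {doc.doc_id!r} in corpus")
        seen.add(doc.doc_id)
        index.add_document(doc)
    return index


def make_query_plan(topic: TopicRecord, index_kind: str = "metadata",
                    synonyms: SynonymTable | None = None) -> list[QuerySpec]:
    """The combinatorial query plan: exactly 7 QuerySpecs per topic.

    {query, question, narrative} x {title, abstract section} plus the
    concatenated topic against the whole document.  Synonym expansion,
    when a table is supplied, is applied per source field after
    normalization (queries only — documents are indexed unexpanded).
    """
    if index_kind not in ("metadata", "fulltext"):
        raise ConfigurationError(f"unknown index kind {index_kind!r}")

    def prep(text: str) -> tuple[str, ...]:
        terms = normalize(text)
        if synonyms is not None:
            terms = expand(terms, synonyms)
        return tuple(terms)

    per_field = {
        "query": prep(topic.query),
        "question": prep(topic.question),
        "narrative": prep(topic.narrative),
    }
    plan = [
        QuerySpec(topic.number, source, target, per_field[source])
        for source in ("query", "question", "narrative")
        for target in ("title", "abstract")
    ]
    concat = per_field["query"] + per_field["question"] + per_field["narrative"]
    plan.append(QuerySpec(topic.number, "all", "whole", concat))
    return plan


def _passes_cutoff(date: datetime.date | None, cutoff: datetime.date | None,
                   keep_undated: bool) -> bool:
    if cutoff is None:
        return True
    if date is None:
        return keep_undated
    return date >= cutoff


def _score_spec(index: InvertedIndex, spec: QuerySpec, model: str, params,
                scores: dict[str, float]) -> None:
    stats = index.fields[spec.target]
    n_docs = stats.n_docs
    avg_len = stats.avg_len
    total = stats.total_terms
    if model == "lmd":
        # every document receives smoothed probability mass, so the whole
        # collection is scored, not just postings
        valid = [t for t in spec.terms if stats.coll_freq(t) > 0]
        if not valid:
            return
        cfs = {t: stats.coll_freq(t) for t in valid}
        for doc_id, dlen in stats.doc_len.items():
            s = 0.0
            for t in valid:
                s += term_weight(model, params, tf=stats.tf(t, doc_id),
                                 doc_len=dlen, n_docs=n_docs, avg_len=avg_len,
                                 doc_freq=0, coll_freq=cfs[t], total_terms=total)
            scores[doc_id] = scores.get(doc_id, 0.0) + s
    else:
        for t in spec.terms:
            plist = stats.postings.get(t)
            if not plist:
                continue
            df = len(plist)
            cf = sum(plist.values())
            for doc_id, tf in plist.items():
                w = term_weight(model, params, tf=tf,
                                doc_len=stats.doc_len[doc_id], n_docs=n_docs,
                                avg_len=avg_len, doc_freq=df, coll_freq=cf,
                                total_terms=total)
                scores[doc_id] = scores.get(doc_id, 0.0) + w


def search(index: InvertedIndex, plan: Sequence[QuerySpec], model: str, params,
           top_k: int = 1000, cutoff: datetime.date | None = None,
           keep_undated: bool = True, tag: str | None = None) -> RankedList:
    """Execute a query plan: sum the model's score over all specs.

    Documents dated strictly before ``cutoff`` are excluded; undated
    documents are retained unless ``keep_undated`` is False.  Results are
    sorted score descending, doc_id ascending on ties, truncated to
    ``top_k``.
    """
    if model not in MODEL_HANDLES:
        raise ConfigurationError(f"unknown weighting model {model!r}")
    if top_k < 1:
        raise ConfigurationError(f"top_k must be >= 1, got {top_k}")
    if not plan:
        raise ConfigurationError("empty query plan")
    topic = plan[0].topic
    scores: dict[str, float] = {}
    for spec in plan:
        if spec.topic != topic:
            raise ConfigurationError("query plan mixes topics")
        _score_spec(index, spec, model, params, scores)
    filtered = {
        d: s for d, s in scores.items()
        if _passes_cutoff(index.dates.get(d), cutoff, keep_undated)
    }
    return RankedList.from_scores(topic, filtered, tag=tag or model, top_k=top_k)


def fit_params(index: InvertedIndex, topics: Sequence[TopicRecord],
               qrels: JudgmentSet, model: str, grid: Sequence,
               folds: int = 5, top_k: int = 100,
               synonyms: SynonymTable | None = None,
               cutoff: datetime.date | None = None):
    """Grid-search model parameters by cross-validated P@10.

    Topics are partitioned deterministically into ``folds`` folds by
    topic number modulo the fold count; for every grid point the mean
    P@10 over held-out folds is computed, and the argmax returned (ties
    broken by grid order).
    """
    from .evaluation import precision_at_k

    grid = list(grid)
    if not grid:
        raise ConfigurationError("empty parameter grid")
    usable = [t for t in topics
              if any(g >= 1 for g in qrels.judged_docs(t.number).values())]
    if len(usable) < folds:
        raise ConfigurationError(
            f"need at least {folds} topics with a relevant judgment, "
            f"got {len(usable)}")

    fold_of = {t.number: t.number % folds for t in usable}
    plans = {t.number: make_query_plan(t, index.kind, synonyms) for t in usable}

    best, best_score = None, -1.0
    for params in grid:
        fold_means = []
        for f in range(folds):
            held_out = [t for t in usable if fold_of[t.number] == f]
            if not held_out:
                continue
            vals = []
            for t in held_out:
                run = search(index, plans[t.number], model, params,
                             top_k=top_k, cutoff=cutoff)
                vals.append(precision_at_k(run, qrels, 10))
            fold_means.append(sum(vals) / len(vals))
        score = sum(fold_means) / len(fold_means)
        if score > best_score + 1e-12:
            best, best_score = params, score
    return best


def save_index(index: InvertedIndex, path: str | Path) -> None:
    """Persist the index as versioned JSON (terms, postings, dates)."""
    payload = {
        "format": INDEX_FORMAT,
        "version": INDEX_VERSION,
        "kind": index.kind,
        "dates": {d: (dt.isoformat() if dt else None) for d, dt in index.dates.items()},
        "fields": {
            name: {"doc_len": fs.doc_len, "postings": fs.postings}
            for name, fs in index.fields.items()
        },
    }
    Path(path).write_text(json.dumps(payload), encoding="utf-8")


def load_index(path: str | Path) -> InvertedIndex:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if payload.get("format") != INDEX_FORMAT:
        raise ConfigurationError(f"{path}: not a {INDEX_FORMAT} file")
    if payload.get("version") != INDEX_VERSION:
        raise ConfigurationError(
            f"{path}: unsupported index version {payload.get('version')}")
    index = InvertedIndex(payload["kind"])
    for name, fs in payload["fields"].items():
        stats = index.fields[name]
        stats.doc_len = dict(fs["doc_len"])
        stats.postings = {t: dict(p) for t, p in fs["postings"].items()}
    index.dates = {
        d: (datetime.date.fromisoformat(v) if v else None)
        for d, v in payload["dates"].items()
    }
    return index
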