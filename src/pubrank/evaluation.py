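"""Graded-relevance evaluation in the trec_eval tradition.

Metrics over a ranked list and a set of graded judgments (0/1/2):

* **P@K** — fraction of the top K that is judged relevant (grade >= 1);
  unjudged documents count as nonrelevant, short lists are padded.
* **NDCG@K** — DCG with gain = raw grade and 1/log2(rank+1) discount,
  normalized by the ideal DCG over all judged grades of the topic
  ("ndcg_cut" convention).
* **AP / MAP** — mean of precision at each relevant retrieved document,
  divided by the total number of judged-relevant documents R.
* **Bpref** — binary preference: for each relevant retrieved document r,
  1 - min(#judged-nonrelevant ranked above r, R) / min(R, N), averaged
  over R; unjudged documents are invisible to the "ranked above" count
  (condensed over judged documents only), which makes the measure robust
  under incomplete pooled judging.

Reports macro-average over the topics that have at least one judgment.
The recency profile histograms the publication dates of judged-relevant
documents (the characteristic outbreak-literature pattern is a sharp
concentration of relevant articles near the event).
"""

from __future__ import annotations

import datetime
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .corpus_io import DocumentRecord, IntegrityError, JudgmentSet, RankedList

__all__ = [
    "precision_at_k",
    "ndcg_at_k",
    "average_precision",
    "bpref",
    "MetricsReport",
    "evaluate_run",
    "RecencyProfile",
    "recency_profile",
    "write_report",
]

DEFAULT_K_VALUES = (5, 10, 20)


def precision_at_k(run: RankedList, qrels: JudgmentSet, k: int) -> float:
    """Fraction of the top k that is relevant (grade >= 1)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    hits = sum(1 for e in run.entries[:k] if qrels.is_relevant(run.topic, e.doc_id))
    return hits / k


def ndcg_at_k(run: RankedList, qrels: JudgmentSet, k: int) -> float:
    """NDCG with gain = grade and log2(rank+1) discount; 0 when no judged
    document of the topic is relevant."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    dcg = 0.0
    for i, e in enumerate(run.entries[:k]):
        grade = qrels.grade(run.topic, e.doc_id) or 0
        dcg += grade / math.log2(i + 2)
    ideal = sorted(qrels.judged_docs(run.topic).values(), reverse=True)
    idcg = sum(g / math.log2(i + 2) for i, g in enumerate(ideal[:k]))
    return dcg / idcg if idcg > 0 else 0.0


def average_precision(run: RankedList, qrels: JudgmentSet) -> float:
    """AP over binarized relevance; 0 (with a warning) when the topic has
    no judged-relevant documents."""
    judged = qrels.judged_docs(run.topic)
    n_rel = sum(1 for g in judged.values() if g >= 1)
    if n_rel == 0:
        warnings.warn(f"topic {run.topic}: no relevant judgments, AP set to 0",
                      stacklevel=2)
        return 0.0
    hits = 0
    total = 0.0
    for i, e in enumerate(run.entries, start=1):
        if judged.get(e.doc_id, 0) >= 1:
            hits += 1
            total += hits / i
    return total / n_rel


def bpref(run: RankedList, qrels: JudgmentSet) -> float:
    """Binary preference over the condensed (judged-only) ranking."""
    judged = qrels.judged_docs(run.topic)
    n_rel = sum(1 for g in judged.values() if g >= 1)
    n_nonrel = sum(1 for g in judged.values() if g == 0)
    if n_rel == 0:
        warnings.warn(f"topic {run.topic}: no relevant judgments, Bpref set to 0",
                      stacklevel=2)
        return 0.0
    if n_nonrel == 0:
        # every judged document is relevant: any relevant retrieved scores 1
        retrieved_rel = sum(1 for e in run.entries if judged.get(e.doc_id, 0) >= 1)
        return retrieved_rel / n_rel
    total = 0.0
    nonrel_above = 0
    for e in run.entries:
        grade = judged.get(e.doc_id)
        if grade is None:
            continue
        if grade >= 1:
            total += 1.0 - min(nonrel_above, n_rel) / min(n_rel, n_nonrel)
        else:
            nonrel_above += 1
    return total / n_rel


@dataclass
class MetricsReport:
    """Per-topic and macro-averaged evaluation results."""

    k_values: tuple[int, ...]
    per_topic: dict[int, dict[str, float]] = field(default_factory=dict)
    averages: dict[str, float] = field(default_factory=dict)

    def metric(self, name: str, topic: int | None = None) -> float:
        if topic is None:
            return self.averages[name]
        return self.per_topic[topic][name]


def evaluate_run(runs: Sequence[RankedList], qrels: JudgmentSet,
                 k_values: Sequence[int] = DEFAULT_K_VALUES) -> MetricsReport:
    """Evaluate a run (one RankedList per topic) against graded judgments.

    Macro-averages over the evaluated topics; topics without any judgment
    are skipped.  Raises IntegrityError when no run topic has judgments.
    """
    judged_topics = set(qrels.topics())
    report = MetricsReport(k_values=tuple(k_values))
    for run in sorted(runs, key=lambda r: r.topic):
        if run.topic not in judged_topics:
            continue
        judged = qrels.judged_docs(run.topic)
        n_rel = sum(1 for g in judged.values() if g >= 1)
        row: dict[str, float] = {}
        for k in k_values:
            row[f"P@{k}"] = precision_at_k(run, qrels, k)
            row[f"NDCG@{k}"] = ndcg_at_k(run, qrels, k)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["AP"] = average_precision(run, qrels)
            row["Bpref"] = bpref(run, qrels)
        row["num_rel"] = float(n_rel)
        row["num_rel_ret"] = float(
            sum(1 for e in run.entries if judged.get(e.doc_id, 0) >= 1))
        report.per_topic[run.topic] = row
    if not report.per_topic:
        raise IntegrityError("no overlap between run topics and judged topics")
    n = len(report.per_topic)
    names = next(iter(report.per_topic.values())).keys()
    report.averages = {
        ("MAP" if name == "AP" else name):
            sum(row[name] for row in report.per_topic.values()) / n
        for name in names
    }
    return report


@dataclass
class RecencyProfile:
    """Histogram of publication dates of judged-relevant documents."""

    bin_width_days: int
    bins: dict[datetime.date, int] = field(default_factory=dict)
    n_dated: int = 0
    n_undated: int = 0


def recency_profile(qrels: JudgmentSet, corpus: Sequence[DocumentRecord],
                    min_grade: int = 2, bin_width_days: int = 7) -> RecencyProfile:
    """Distribution over time of the documents judged at ``min_grade`` or
    above.  Documents without a parseable date are counted separately."""
    if bin_width_days < 1:
        raise ValueError("bin_width_days must be >= 1")
    by_id = {d.doc_id: d for d in corpus}
    dates = []
    undated = 0
    seen: set[str] = set()
    for (_topic, doc_id), grade in qrels.items():
        if grade < min_grade or doc_id in seen:
            continue
        seen.add(doc_id)
        doc = by_id.get(doc_id)
        if doc is None:
            continue
        if doc.publish_date is None:
            undated += 1
        else:
            dates.append(doc.publish_date)
    profile = RecencyProfile(bin_width_days=bin_width_days, n_undated=undated)
    if not dates:
        return profile
    origin = min(dates)
    for d in dates:
        offset = (d - origin).days // bin_width_days
        start = origin + datetime.timedelta(days=offset * bin_width_days)
        profile.bins[start] = profile.bins.get(start, 0) + 1
    profile.n_dated = len(dates)
    return profile


def write_report(report: MetricsReport, path: str | Path) -> None:
    """Emit the report as delimited text keyed by (metric, topic|'all'),
    mirroring the classic evaluator layout for diffability."""
    lines = []
    for topic in sorted(report.per_topic):
        for name, value in report.per_topic[topic].items():
            lines.append(f"{name}\t{topic}\t{value:.4f}")
    for name, value in report.averages.items():
        lines.append(f"{name}\tall\t{value:.4f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
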