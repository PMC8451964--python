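"""Deterministic synthetic corpora, topics and judgments.

Real outbreak-literature collections are heterogeneous: some records are
title-only, some carry large full texts, dates range from full ISO days
to bare years, and graded judgments cover only a pooled subset of the
collection.  This module emulates those properties so every pipeline
stage is testable without downloading anything.

The generative model: a vocabulary is partitioned into per-theme term
sets and a Zipf-distributed background; each document belongs to one
latent theme and draws its tokens from a mixture of the theme set and
the background, with a per-document mixing weight so topical saturation
varies.  One topic is emitted per theme, phrased from that theme's
terms.  Graded relevance is defined *by the generator's rule* — the
fraction of the topic's theme terms present in title + abstract: grade 2
at high overlap, grade 1 at partial overlap, grade 0 otherwise — so the
ground truth is independent of any system under test.  Vocabulary tokens
carry digits, which makes them fixed points of the normalization
pipeline (no stemming), keeping the rule exactly recomputable from the
written files.

``adversarial_pair`` constructs two runs whose top-3 sets are disjoint
per topic yet both contain relevant documents — the regime where
reciprocal rank fusion provably helps.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import DocumentRecord, JudgmentSet, RankedList, RunEntry, TopicRecord
from .index_core import ConfigurationError
from .text_pipeline import normalize

__all__ = ["SyntheticSpec", "generate", "adversarial_pair", "corpus_by_id"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the synthetic collection.

    Defaults give a small but fully featured collection: 3 themes x 20
    documents, mixed-precision dates straddling the outbreak cutoff, a
    fraction of records with full text, and pooled (incomplete) judging.
    """

    vocab_size: int = 500
    n_themes: int = 3
    docs_per_theme: int = 20
    terms_per_theme: int = 8
    title_len: tuple[int, int] = (4, 8)
    abstract_len: tuple[int, int] = (25, 50)
    fulltext_len: tuple[int, int] = (80, 160)
    fulltext_fraction: float = 0.4
    date_range: tuple[datetime.date, datetime.date] = (
        datetime.date(2019, 9, 1), datetime.date(2020, 6, 30))
    missing_date_fraction: float = 0.05
    #: per-document theme-mixture weight is drawn uniformly from this range
    theme_mix: tuple[float, float] = (0.02, 0.45)
    #: overlap thresholds of the relevance rule: grade 2 at >= hi, 1 at >= lo
    overlap_hi: float = 0.75
    overlap_lo: float = 0.35
    #: judged nonrelevant off-theme documents pooled per topic
    pool_nonrel: int = 10
    zipf_exponent: float = 1.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.vocab_size, self.n_themes, self.docs_per_theme,
               self.terms_per_theme) <= 0:
            raise ConfigurationError("all counts must be positive")
        if self.n_themes * self.terms_per_theme >= self.vocab_size:
            raise ConfigurationError(
                "theme terms exhaust the vocabulary; enlarge vocab_size")
        for frac in (self.fulltext_fraction, self.missing_date_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError("fractions must lie in [0, 1]")
        if not 0.0 < self.overlap_lo < self.overlap_hi <= 1.0:
            raise ConfigurationError("need 0 < overlap_lo < overlap_hi <= 1")


def _vocabulary(spec: SyntheticSpec) -> tuple[list[list[str]], list[str]]:
    # tokens contain digits so normalization leaves them unchanged
    words = [f"w{i:04d}" for i in range(spec.vocab_size)]
    theme_terms = [
        words[t * spec.terms_per_theme:(t + 1) * spec.terms_per_theme]
        for t in range(spec.n_themes)
    ]
    background = words[spec.n_themes * spec.terms_per_theme:]
    return theme_terms, background


def _draw_terms(rng: np.random.Generator, n: int, theme: Sequence[str],
                background: Sequence[str], bg_probs: np.ndarray,
                mix: float) -> list[str]:
    take_theme = rng.random(n) < mix
    theme_idx = rng.integers(0, len(theme), size=n)
    bg_idx = rng.choice(len(background), size=n, p=bg_probs)
    return [theme[theme_idx[i]] if take_theme[i] else background[bg_idx[i]]
            for i in range(n)]


def _overlap(doc: DocumentRecord, theme: Sequence[str]) -> float:
    doc_terms = set(normalize(doc.title + " " + doc.abstract))
    return sum(1 for t in theme if t in doc_terms) / len(theme)


def generate(spec: SyntheticSpec) -> tuple[list[DocumentRecord],
                                           list[TopicRecord], JudgmentSet]:
    """Generate (corpus, topics, qrels); pure function of the spec.

    Guarantees per topic: at least one grade-2 judgment (an anchor
    document containing every theme term) and at least one grade-0
    judgment (pooled off-theme documents, which share no theme terms).
    """
    rng = np.random.default_rng(spec.seed)
    theme_terms, background = _vocabulary(spec)
    ranks = np.arange(1, len(background) + 1, dtype=float)
    bg_probs = ranks ** -spec.zipf_exponent
    bg_probs /= bg_probs.sum()
    span_days = (spec.date_range[1] - spec.date_range[0]).days

    corpus: list[DocumentRecord] = []
    theme_of: dict[str, int] = {}
    for theme_id in range(spec.n_themes):
        theme = theme_terms[theme_id]
        for j in range(spec.docs_per_theme):
            doc_id = f"doc-{theme_id}-{j:03d}"
            anchor = j == 0
            mix = rng.uniform(*spec.theme_mix)
            n_title = int(rng.integers(spec.title_len[0], spec.title_len[1] + 1))
            n_abs = int(rng.integers(spec.abstract_len[0], spec.abstract_len[1] + 1))
            title_terms = _draw_terms(rng, n_title, theme, background, bg_probs, mix)
            abs_terms = _draw_terms(rng, n_abs, theme, background, bg_probs, mix)
            if anchor:
                # the anchor carries every theme term: guaranteed grade 2
                abs_terms = list(theme) + abs_terms
            full_text = None
            if rng.random() < spec.fulltext_fraction:
                n_full = int(rng.integers(spec.fulltext_len[0],
                                          spec.fulltext_len[1] + 1))
                full_text = " ".join(
                    _draw_terms(rng, n_full, theme, background, bg_probs, mix))
            if rng.random() < spec.missing_date_fraction:
                date = None
            else:
                date = spec.date_range[0] + datetime.timedelta(
                    days=int(rng.integers(0, span_days + 1)))
            doc = DocumentRecord(
                doc_id=doc_id,
                title=" ".join(title_terms),
                abstract=" ".join(abs_terms),
                full_text=full_text,
                publish_date=date,
                source=f"synthetic-theme-{theme_id}",
            )
            corpus.append(doc)
            theme_of[doc_id] = theme_id

    topics: list[TopicRecord] = []
    for theme_id in range(spec.n_themes):
        theme = theme_terms[theme_id]
        topics.append(TopicRecord(
            number=theme_id + 1,
            query=" ".join(theme[:3]),
            question="what is known about " + " ".join(theme[:4]),
            narrative=("studies discussing " + " ".join(theme)
                       + " including mechanisms and outcomes"),
        ))

    qrels = JudgmentSet()
    for topic in topics:
        theme_id = topic.number - 1
        theme = theme_terms[theme_id]
        same_theme = [d for d in corpus if theme_of[d.doc_id] == theme_id]
        for doc in same_theme:
            frac = _overlap(doc, theme)
            if frac >= spec.overlap_hi:
                grade = 2
            elif frac >= spec.overlap_lo:
                grade = 1
            else:
                grade = 0
            qrels.add(topic.number, doc.doc_id, grade)
        # pooled off-theme documents: no theme-term overlap, grade 0
        others = [d.doc_id for d in corpus if theme_of[d.doc_id] != theme_id]
        pick = rng.choice(len(others), size=min(spec.pool_nonrel, len(others)),
                          replace=False)
        for i in sorted(int(p) for p in pick):
            qrels.add(topic.number, others[i], 0)
    return corpus, topics, qrels


def corpus_by_id(corpus: Sequence[DocumentRecord]) -> dict[str, DocumentRecord]:
    return {d.doc_id: d for d in corpus}


def adversarial_pair(spec: SyntheticSpec, depth: int = 10
                     ) -> tuple[list[RankedList], list[RankedList]]:
    """Two runs with disjoint per-topic top-3 sets, each holding relevant
    documents, so reciprocal rank fusion provably improves P@3.

    Per topic, run A's top 3 are (relevant, relevant, nonrelevant) and
    run B's are (relevant, relevant, nonrelevant) with entirely different
    documents; fusing aligns the four relevant documents ahead of the
    nonrelevant ones, lifting P@3 from 2/3 to 1.
    """
    if spec.n_themes < 2:
        raise ConfigurationError("adversarial_pair needs at least 2 themes")
    _corpus, topics, qrels = generate(spec)
    runs_a: list[RankedList] = []
    runs_b: list[RankedList] = []
    for topic in topics:
        judged = qrels.judged_docs(topic.number)
        rel = sorted(d for d, g in judged.items() if g >= 1)
        nonrel = sorted(d for d, g in judged.items() if g == 0)
        if len(rel) < 4 or len(nonrel) < 2:
            raise ConfigurationError(
                f"topic {topic.number}: need >= 4 relevant and >= 2 "
                f"nonrelevant judged documents for the construction")
        head_a = [rel[0], rel[1], nonrel[0]]
        head_b = [rel[2], rel[3], nonrel[1]]
        used = set(head_a) | set(head_b)
        tail = [d for d in sorted(judged) if d not in used]
        # tails are split so every document appears in exactly one run:
        # no tail document can accumulate score from both lists and
        # overtake the fused heads
        order_a = head_a + tail[0::2]
        order_b = head_b + tail[1::2]
        runs_a.append(RankedList(
            topic.number,
            [RunEntry(d, 1.0 / r, r) for r, d in enumerate(order_a[:depth], 1)],
            tag="advA"))
        runs_b.append(RankedList(
            topic.number,
            [RunEntry(d, 1.0 / r, r) for r, d in enumerate(order_b[:depth], 1)],
            tag="advB"))
    return runs_a, runs_b
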