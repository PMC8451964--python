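"""First-stage probabilistic term-weighting models.

Three bag-of-words weighting schemes behind one scoring contract, each
mapping (term frequency, document length, collection statistics) to a
per-term contribution that the search layer sums over query terms:

**BM25** — tf-idf with term-frequency saturation (k1) and document-length
normalization (b)::

    w = idf(n_t, N) * tf * (k1 + 1) / (tf + k1 * (1 - b + b * |d|/avg_l))
    idf = ln(1 + (N - n_t + 0.5) / (n_t + 0.5))

The idf is the nonnegative Lucene-style variant, matching the
Elasticsearch lineage of this pipeline and avoiding negative weights for
very common terms.

**DFR** — divergence from randomness with a geometric (Bose-Einstein
approximation) randomness model and H2-style term-frequency
normalization.  The information content of observing tfn occurrences
when the collection-wide expectation is lambda = cf / N::

    tfn = tf * log2(1 + avg_l / |d|)
    w   = k * ( log2(1 + lambda) + tfn * log2((1 + lambda) / lambda) )

**LMD** — Dirichlet-smoothed query likelihood.  Per-term log probability
of the query term under the smoothed document language model::

    w = ln( (tf + mu * p(t|D)) / (|d| + mu) ),   p(t|D) = cf / total_terms

LMD scores are negative log-probabilities summed over query terms; terms
unseen in the whole collection are skipped (p(t|D)=0 would force -inf).
Within each model the log base is a rank-invariant convention: natural
log for BM25/LMD, log2 for DFR.

Default parameters are the untuned round-one values: k1=1.2, b=0.75,
mu=2000, DFR k=1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BM25Params",
    "DFRParams",
    "LMDParams",
    "bm25_weight",
    "dfr_weight",
    "lmd_weight",
    "MODEL_HANDLES",
    "default_params",
    "term_weight",
]


class InvalidStatistics(ValueError):
    """Collection statistics violate a model precondition."""


@dataclass(frozen=True)
class BM25Params:
    """k1: term-frequency saturation (>= 0); b: length normalization in [0, 1]."""

    k1: float = 1.2
    b: float = 0.75

    def __post_init__(self) -> None:
        if self.k1 < 0:
            raise ValueError(f"k1 must be nonnegative, got {self.k1}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"b must be in [0, 1], got {self.b}")


@dataclass(frozen=True)
class DFRParams:
    """model: randomness model id; k: positive scale on the information content."""

    model: str = "geometric"
    k: float = 1.0

    SUPPORTED = ("geometric", "poisson")

    def __post_init__(self) -> None:
        if self.model not in self.SUPPORTED:
            raise ValueError(f"unsupported randomness model {self.model!r}")
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")


@dataclass(frozen=True)
class LMDParams:
    """mu: Dirichlet pseudo-count controlling the amount of smoothing (> 0)."""

    mu: float = 2000.0

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")


def bm25_weight(tf: float, doc_len: float, n_docs: int, avg_len: float,
                doc_freq: int, params: BM25Params) -> float:
    """BM25 contribution of one query-term occurrence; 0 when tf = 0."""
    if avg_len <= 0:
        raise InvalidStatistics(f"avg_len must be positive, got {avg_len}")
    if doc_freq > n_docs:
        raise InvalidStatistics("doc_freq cannot exceed the collection size")
    if tf <= 0:
        return 0.0
    idf = math.log(1.0 + (n_docs - doc_freq + 0.5) / (doc_freq + 0.5))
    denom = tf + params.k1 * (1.0 - params.b + params.b * doc_len / avg_len)
    return idf * tf * (params.k1 + 1.0) / denom


def dfr_weight(tf: float, doc_len: float, n_docs: int, avg_len: float,
               coll_freq: float, params: DFRParams) -> float:
    """DFR (geometric/Bose-Einstein) contribution; 0 when tf = 0.

    The Poisson model id falls back to the same Bose-Einstein information
    content with lambda = cf/N; both are monotone in the normalized tf.
    """
    if tf <= 0:
        return 0.0
    if coll_freq <= 0:
        raise InvalidStatistics("coll_freq must be positive when tf > 0")
    if n_docs <= 0:
        raise InvalidStatistics("empty collection")
    lam = coll_freq / n_docs
    if doc_len > 0:
        tfn = tf * math.log2(1.0 + avg_len / doc_len)
    else:
        tfn = tf
    return params.k * (math.log2(1.0 + lam) + tfn * math.log2((1.0 + lam) / lam))


def lmd_weight(tf: float, doc_len: float, total_terms: float, coll_freq: float,
               params: LMDParams) -> float:
    """Dirichlet-smoothed per-term query log-likelihood.

    Returns 0 for terms absent from the entire collection (cf = 0); these
    carry no evidence and are skipped by convention.
    """
    if total_terms <= 0:
        raise InvalidStatistics("collection has no terms")
    if coll_freq <= 0:
        return 0.0
    p_coll = coll_freq / total_terms
    return math.log((tf + params.mu * p_coll) / (doc_len + params.mu))


#: model handle -> parameter class, for config-driven construction
MODEL_HANDLES = {"bm25": BM25Params, "dfr": DFRParams, "lmd": LMDParams}


def default_params(model: str):
    """Default (untuned) parameters for a model handle."""
    try:
        return MODEL_HANDLES[model]()
    except KeyError:
        raise KeyError(f"unknown weighting model {model!r}") from None


def term_weight(model: str, params, *, tf: float, doc_len: float, n_docs: int,
                avg_len: float, doc_freq: int, coll_freq: float,
                total_terms: float) -> float:
    """Uniform dispatch used by the search layer and the brute-force oracle."""
    if model == "bm25":
        return bm25_weight(tf, doc_len, n_docs, avg_len, doc_freq, params)
    if model == "dfr":
        return dfr_weight(tf, doc_len, n_docs, avg_len, coll_freq, params)
    if model == "lmd":
        return lmd_weight(tf, doc_len, total_terms, coll_freq, params)
    raise KeyError(f"unknown weighting model {model!r}")
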