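# Methods

## Retrieval model

Documents are ranked in up to three stages: probabilistic first-stage
weighting over an inverted index, an optional second-stage rescoring of the
top of the first-stage list, and fusion of the resulting ranked lists.

### Preprocessing

All document and topic text passes through one deterministic pipeline:
lower-casing; replacement of every character outside `[a-z0-9-]` by
whitespace; whitespace tokenization; Porter stemming. The stemmer is the
classic 1980 suffix-stripping algorithm (five rule steps over the
consonant–vowel measure, longest-suffix matching), implemented in
`pubrank._porter` and checked against the algorithm's published worked
examples. Stemming applies only to purely alphabetic tokens: identifiers
that carry digits or hyphens (`covid-19`, `sars-cov-2`) are exactly the
domain vocabulary that must not be mangled, so they pass through unchanged.
No stopword removal is performed; the weighting models already discount
ubiquitous terms, and dropping tokens would silently change collection
statistics. Tokens consisting only of hyphens are degenerate and dropped.

Synonym expansion applies to queries only (never at indexing): after each
query term that triggers a group in the synonym table, the other group
members are appended once. The shipped table is a minimal COVID cluster in
an editable plain-text config (one comma-separated group per line); the
mechanism, not the particular list, is the point.

### Indexes and the combinatorial query strategy

Two index flavours are built from the same corpus: *metadata*
(title + abstract) and *fulltext* (title + abstract + body). Each stores
three searchable sections — `title`, `abstract` (for the fulltext index this
section is abstract followed by full text) and `whole` (title then
abstract section) — with per-section postings `f(t,d)`, document lengths,
average length, document count, document frequency `n_t` and collection
frequency `cf`.

A topic contributes seven queries: each of its three fields against each of
`title` and `abstract`, plus the concatenation of all three fields against
`whole`. Per-document scores are summed over the seven queries without
weights. Scores from the two index flavours are never added to each other;
they form separate runs combined later by rank fusion, because the two
collections' statistics (and hence score scales) are incommensurable.

A search-time date cutoff drops documents published strictly before a given
day (default boundary 2019-12-01, the onset of the outbreak literature);
the boundary day itself is retained. Documents with no parseable date are
kept by default — silently discarding undated records would hide corpus
defects — and can be dropped with a flag.

### Weighting models

All three models share one per-term contract (term frequency, document
length, collection statistics → real weight), summed over query-term
occurrences (duplicate query terms count twice):

- **BM25**: `w = idf · tf(k1+1)/(tf + k1(1−b+b·|d|/avg_l))` with the
  nonnegative idf `ln(1 + (N−n_t+0.5)/(n_t+0.5))`. The idf variant follows
  the Lucene/Elasticsearch lineage of this pipeline design and avoids
  negative weights for terms in more than half the collection. Defaults
  `k1 = 1.2`, `b = 0.75` (the standard untuned values).
- **DFR**: geometric (Bose–Einstein approximation) randomness model with
  H2-style length normalization `tfn = tf·log2(1 + avg_l/|d|)` and
  information content `k·[log2(1+λ) + tfn·log2((1+λ)/λ)]`, `λ = cf/N`,
  default scale `k = 1`. The randomness-model id is a config choice;
  geometric is the default instantiation.
- **LMD**: Dirichlet-smoothed query log-likelihood
  `ln((tf + μ·p(t|D))/(|d| + μ))` with `p(t|D) = cf / total terms` and
  default `μ = 2000`. Because smoothing gives every document nonzero
  probability mass, LMD scores the whole collection for any query term seen
  in the collection; terms unseen everywhere are skipped (their smoothed
  probability would be zero and the log-likelihood −∞, carrying no ranking
  information).

Log bases are per-model conventions (natural log for BM25/LMD, log2 for
DFR); rankings are invariant to the base within a model.

Parameter tuning is a grid search maximizing P@10 under deterministic
5-fold cross-validation (topics assigned to folds by topic number modulo
the fold count; per grid point the held-out fold means are averaged; ties
broken by grid order).

### Ordering and determinism

Every ranked list is sorted score-descending with ties broken by document
id ascending, everywhere in the pipeline. Reciprocal rank fusion
accumulates each document's contributions in sorted-rank order before
summing, which makes fused scores bit-for-bit independent of the order of
the input lists (floating-point addition is not associative, and tied
scores would otherwise order-flip). End-to-end runs on identical inputs are
byte-identical; run files print scores at 6 decimal places, enough for a
lossless round-trip at fixture scale.

### Second stage and fusion

The second-stage scorer is a contract: any deterministic total callable
`(topic, document) → finite score`. The shipped scorers are lexical-overlap
mocks (fraction of a topic field's normalized terms present in
title + abstract, range [0, 1]) registered as `overlap-query`,
`overlap-question`, `overlap-narrative`; production rerankers (fine-tuned
transformer classifiers) are adapters satisfying the same contract and are
deliberately out of scope. A second registry slot exists for pairwise
(LambdaMART-style) rerankers; none is shipped, and recipes requiring one
fail fast.

Reciprocal rank fusion uses `k = 60` by default. Feature-level fusion
assembles, per (topic, document), the similarity scores of all contributing
models; documents absent from one model's list get that model's per-topic
minimum minus a fixed offset of 1 ("worse than anything it retrieved") with
an imputation flag. Labels binarize the graded judgments (grades 1 and 2
are both relevant); unjudged rows are excluded from training but still
scored. Features are z-scored over training rows (the models' score scales
differ by orders of magnitude), and the L2-penalized log-likelihood (bias
unpenalized) is maximized by a deterministic full-batch quasi-Newton
optimizer (L-BFGS) from zero initialization — full-batch and deterministic
for exact reproducibility, quasi-Newton rather than plain gradient ascent
for reliable convergence to reference-optimizer loss at tight tolerance.

### Run recipes

M1 = BM25 on the metadata index; M2 = RRF of {BM25, DFR, LMD} × {metadata,
fulltext} (six lists); M3 = RRF of the registered rerankers applied to the
top-k of M2 (default depth 5000, clipped to corpus size); M4 = RRF(M2, M3);
M5 = pairwise plug-in slot; M6 = logistic fusion over the constituent
scores of M2 and M3; M7 = RRF(M2, M3, M6). Which lists feed M2 is
configurable through custom recipe DAGs, validated (unique names,
resolvable references, registered scorers, acyclicity) before any
computation runs.

## Evaluation

P@K, NDCG@K (gain = raw grade 0/1/2, discount `1/log2(rank+1)`, ideal DCG
from all judged grades of the topic — the `ndcg_cut` convention), AP/MAP,
and Bpref (condensed over judged documents only, so unjudged documents are
invisible to the "ranked above" count). Unjudged documents count as
nonrelevant for P@K/AP/NDCG. Macro-averaging covers topics with at least
one judgment. Topics with no relevant judgments score 0 with a warning.
The recency profile histograms the publication dates of judged-relevant
documents at a configurable bin width; the exponential-decay fit of that
profile is not implemented, only the profile itself.

## Synthetic collections

The generator emulates the features the pipeline is sensitive to: a
vocabulary split into disjoint per-theme term sets plus a Zipf background
(exponent 1.3); one document per (theme, index) drawing tokens from a
mixture of its theme set and the background with a per-document mixing
weight uniform on [0.02, 0.45], so topical saturation varies; title /
abstract / full-text lengths of 4–8 / 25–50 / 80–160 tokens with 40% of
documents carrying full text; dates uniform over 2019-09-01..2020-06-30
(straddling the outbreak cutoff) with 5% missing; and pooled judging (all
same-theme documents plus 10 off-theme documents per topic, the rest
unjudged). Relevance is defined by the generator's own rule — the fraction
of a topic's theme terms present in title + abstract, grade 2 at ≥ 0.75,
grade 1 at ≥ 0.35 — so ground truth is independent of the systems under
test, and an anchor document containing every theme term guarantees a
grade-2 judgment per topic. Defaults (3 themes × 20 documents) were chosen
as the smallest collection exhibiting all of these properties at once.

What the generator does **not** emulate: real language (no syntax, no
polysemy, no citation structure, no realistic source mix). Theme terms are
disjoint from the background, so topical signal is much cleaner than in
real corpora — passing tests demonstrate correctness of the machinery, not
retrieval effectiveness on natural text; absolute metric values on these
fixtures sit near the ceiling and should not be read as performance claims.

`adversarial_pair` constructs, per topic, two runs with disjoint top-3 sets
of the form (relevant, relevant, nonrelevant), with the remaining judged
documents split between the runs so no document appears in both. Fusion
then necessarily aligns the four relevant heads ahead of the nonrelevant
ones, lifting P@3 from 2/3 to 1 — an analytically verifiable instance of
the complementary-ranker effect.

## Numerical choices and degenerate inputs

- Score ties: document id ascending, everywhere.
- Date parsing is lenient (year → Jan 1, year-month → first of month,
  otherwise absent); impossible dates become absent rather than errors.
- Zero-length documents: BM25/DFR contribute 0 at tf = 0; the DFR length
  normalization falls back to raw tf at `|d| = 0`; LMD degenerates to the
  collection model `ln p(t|D)`.
- Empty query fields produce empty term sequences but the query plan keeps
  its seven-spec shape.
- Logistic training requires both classes and rejects single-class input;
  constant features get unit scale in the z-score (weight then shrinks to
  0 under the penalty, leaving the closed-form intercept).
- Run-file scores are printed at 6 decimals; reading validates consecutive
  ranks and non-increasing scores.

## Problem sizes

The test suite and the acceptance script run on synthetic collections of
60–120 documents and 2–4 topics, with 50 randomized corpora for the
index-vs-brute-force equivalence check and 150 randomized instances for the
evaluator cross-check — sizes at which brute-force oracles are exact and
the whole suite completes in seconds while still exercising every stage,
including training.

## Known limitations

- No incremental indexing; the index is rebuilt per corpus snapshot.
- No positional or proximity scoring; no weighted-field (BM25F-style)
  variants; the seven query components are summed unweighted.
- The neural rerankers and the pairwise learning-to-rank model exist only
  as plug-in contracts with deterministic mocks.
- Bpref and NDCG follow the classic toolkit conventions; other conventions
  (e.g. exponential NDCG gains) are not provided.
- The recency profile is descriptive only; no decay model is fitted.
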