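import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pubrank.corpus_io import (DocumentRecord, IntegrityError, JudgmentSet,
                               RankedList, RunEntry, TopicRecord)
from pubrank.fusion_rerank import (RRFParams, SCORER_REGISTRY, TrainingError,
                                   assemble_features, fit_logistic,
                                   lexical_overlap_scorer, rerank_topk,
                                   rrf_fuse, score_logistic)


def ranked(topic, doc_ids, tag="r"):
    n = len(doc_ids)
    return RankedList(topic, [RunEntry(d, float(n - i), i + 1)
                              for i, d in enumerate(doc_ids)], tag)


def brute_force_rrf(lists, k):
    """Materialize the full (doc, list) score table and sum it."""
    docs = set()
    for lst in lists:
        docs.update(e.doc_id for e in lst.entries)
    table = {}
    for d in docs:
        for lst in lists:
            r = lst.rank_of(d)
            table[(d, id(lst))] = 0.0 if r is None else 1.0 / (k + r)
    return {d: sum(v for (dd, _), v in table.items() if dd == d) for d in docs}


# ---------------------------------------------------------------------------
# reciprocal rank fusion
# ---------------------------------------------------------------------------


def test_rrf_single_list_rank_one():
    fused = rrf_fuse([ranked(1, ["a"])])
    assert fused.entries[0].score == pytest.approx(1.0 / 61.0)


def test_rrf_two_list_hand_values():
    fused = rrf_fuse([ranked(1, ["a"]), ranked(1, ["a", "b"])])
    scores = {e.doc_id: e.score for e in fused.entries}
    assert scores["a"] == pytest.approx(2.0 / 61.0)
    assert scores["b"] == pytest.approx(1.0 / 62.0)
    assert fused.doc_ids()[0] == "a"


def test_rrf_self_fusion_preserves_order():
    lst = ranked(1, ["c", "a", "b"])
    fused = rrf_fuse([lst, lst, lst])
    assert fused.doc_ids() == ["c", "a", "b"]


def test_rrf_mixed_topics_rejected():
    with pytest.raises(IntegrityError):
        rrf_fuse([ranked(1, ["a"]), ranked(2, ["a"])])


def test_rrf_requires_positive_k():
    with pytest.raises(ValueError):
        RRFParams(k=0.0)


@given(st.data())
@settings(max_examples=60, deadline=None)
def test_rrf_permutation_invariance_and_oracle(data):
    doc_pool = [f"d{i}" for i in range(8)]
    n_lists = data.draw(st.integers(1, 4))
    lists = []
    for _ in range(n_lists):
        docs = data.draw(st.lists(st.sampled_from(doc_pool), unique=True,
                                  min_size=1, max_size=8))
        lists.append(ranked(5, docs))
    k = data.draw(st.sampled_from([10.0, 60.0, 200.0]))
    fused = rrf_fuse(lists, RRFParams(k=k))
    perm = data.draw(st.permutations(lists))
    fused_perm = rrf_fuse(list(perm), RRFParams(k=k))
    assert fused.doc_ids() == fused_perm.doc_ids()
    expected = brute_force_rrf(lists, k)
    for e in fused.entries:
        assert e.score == pytest.approx(expected[e.doc_id], abs=1e-12)


@given(st.data())
@settings(max_examples=60, deadline=None)
def test_rrf_rank_monotonicity(data):
    """Improving a document's rank in one input list never lowers its
    fused score."""
    doc_pool = [f"d{i}" for i in range(6)]
    docs = data.draw(st.lists(st.sampled_from(doc_pool), unique=True,
                              min_size=2, max_size=6))
    other = ranked(1, data.draw(st.lists(st.sampled_from(doc_pool),
                                         unique=True, min_size=1, max_size=6)))
    pos = data.draw(st.integers(1, len(docs) - 1))
    target = docs[pos]
    improved = docs.copy()
    improved[pos - 1], improved[pos] = improved[pos], improved[pos - 1]
    before = {e.doc_id: e.score
              for e in rrf_fuse([ranked(1, docs), other]).entries}
    after = {e.doc_id: e.score
             for e in rrf_fuse([ranked(1, improved), other]).entries}
    assert after[target] >= before[target]


# ---------------------------------------------------------------------------
# second-stage reranking
# ---------------------------------------------------------------------------


@pytest.fixture()
def rerank_fixture():
    topic = TopicRecord(number=1, query="covid",
                        question="covid vaccine trial",
                        narrative="covid vaccine trials")
    corpus = {
        "full": DocumentRecord("full", title="covid vaccine",
                               abstract="randomized trial"),
        "half": DocumentRecord("half", title="covid imaging",
                               abstract="case report"),
        "none": DocumentRecord("none", title="influenza",
                               abstract="surveillance"),
    }
    first = ranked(1, ["none", "half", "full"], tag="first")
    return topic, corpus, first


def test_rerank_constant_scorer_uses_doc_id_tie_rule(rerank_fixture):
    topic, corpus, first = rerank_fixture
    out = rerank_topk(first, lambda t, d: 0.5, topic, corpus, k=2)
    assert out.doc_ids() == ["half", "none"]  # top-2 kept, tie by doc_id
    assert len(out) == 2


def test_rerank_identity_scorer_preserves_order(rerank_fixture):
    topic, corpus, first = rerank_fixture
    first_scores = {e.doc_id: e.score for e in first.entries}
    out = rerank_topk(first, lambda t, d: first_scores[d.doc_id], topic,
                      corpus, k=10)
    assert out.doc_ids() == first.doc_ids()


def test_rerank_lexical_overlap_matches_hand_count(rerank_fixture):
    topic, corpus, first = rerank_fixture
    scorer = lexical_overlap_scorer("question")
    # question terms: covid, vaccin, trial; overlaps: full=3/3, half=1/3, none=0
    out = rerank_topk(first, scorer, topic, corpus, k=3)
    assert out.doc_ids() == ["full", "half", "none"]
    scores = {e.doc_id: e.score for e in out.entries}
    assert scores["full"] == pytest.approx(1.0)
    assert scores["half"] == pytest.approx(1.0 / 3.0)
    assert scores["none"] == 0.0


def test_rerank_missing_doc_raises(rerank_fixture):
    topic, corpus, first = rerank_fixture
    del corpus["half"]
    with pytest.raises(IntegrityError):
        rerank_topk(first, lambda t, d: 0.0, topic, corpus, k=3)


def test_registry_scorers_are_deterministic(rerank_fixture):
    topic, corpus, _ = rerank_fixture
    for name, scorer in SCORER_REGISTRY.items():
        doc = corpus["full"]
        assert scorer(topic, doc) == scorer(topic, doc)
        assert 0.0 <= scorer(topic, doc) <= 1.0


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------


def test_identical_doc_sets_no_imputation():
    runs = {"m1": [ranked(1, ["a", "b"])], "m2": [ranked(1, ["b", "a"])]}
    table = assemble_features(runs)
    assert not table.imputed.any()
    assert table.feature_names == ("m1", "m2")
    assert table.keys == [(1, "a"), (1, "b")]


def test_missing_model_score_imputed_below_minimum():
    runs = {"m1": [ranked(1, ["a", "b"])], "m2": [ranked(1, ["a"])]}
    table = assemble_features(runs)
    j = table.feature_names.index("m2")
    i = table.keys.index((1, "b"))
    assert table.imputed[i, j]
    m2_scores = [table.matrix[table.keys.index((1, d)), j] for d in ("a",)]
    assert table.matrix[i, j] < min(m2_scores)


def test_labels_binarized_and_unjudged_none():
    qrels = JudgmentSet({(1, "a"): 2, (1, "b"): 0})
    runs = {"m": [ranked(1, ["a", "b", "c"])]}
    table = assemble_features(runs, qrels)
    by_doc = dict(zip((d for _, d in table.keys), table.labels))
    assert by_doc == {"a": 1, "b": 0, "c": None}


def test_empty_runs_rejected():
    with pytest.raises(IntegrityError):
        assemble_features({})


# ---------------------------------------------------------------------------
# logistic fusion
# ---------------------------------------------------------------------------


def _table(features, labels, names=None):
    import numpy as np
    from pubrank.fusion_rerank import FeatureTable
    features = np.asarray(features, dtype=float)
    names = names or tuple(f"f{j}" for j in range(features.shape[1]))
    keys = [(1, f"d{i}") for i in range(len(features))]
    return FeatureTable(feature_names=tuple(names), keys=keys,
                        matrix=features, imputed=np.zeros_like(features, bool),
                        labels=list(labels))


def test_separable_feature_gets_positive_weight():
    table = _table([[0.1], [0.2], [0.8], [0.9]], [0, 0, 1, 1])
    model = fit_logistic(table, l2=0.01)
    assert model.weights[0] > 0
    (run,) = score_logistic(model, table)
    assert run.doc_ids() == ["d3", "d2", "d1", "d0"]


def test_constant_feature_intercept_only():
    """With an uninformative feature the fit collapses to the closed-form
    intercept-only model: bias = logit of the base rate."""
    table = _table([[1.0]] * 8, [1, 1, 1, 1, 1, 1, 0, 0])
    model = fit_logistic(table, l2=1.0)
    assert model.weights[0] == pytest.approx(0.0, abs=1e-6)
    assert model.bias == pytest.approx(math.log(6 / 2), abs=1e-6)


def test_single_class_labels_rejected():
    table = _table([[0.0], [1.0]], [1, 1])
    with pytest.raises(TrainingError):
        fit_logistic(table)


def test_unjudged_rows_excluded_from_training_but_scored():
    table = _table([[0.0], [1.0], [0.5]], [0, 1, None])
    model = fit_logistic(table, l2=0.1)
    (run,) = score_logistic(model, table)
    assert set(run.doc_ids()) == {"d0", "d1", "d2"}


def test_loss_matches_reference_optimizer():
    """Penalized log-loss within 1e-6 of scikit-learn's on the identical
    standardized features (sklearn as independent oracle)."""
    from sklearn.linear_model import LogisticRegression

    rng = np.random.default_rng(3)
    x = rng.normal(size=(40, 3))
    logits = 1.5 * x[:, 0] - 1.0 * x[:, 1]
    y = (logits + rng.normal(scale=0.5, size=40) > 0).astype(int)
    l2 = 2.0
    table = _table(x, y.tolist())
    model = fit_logistic(table, l2=l2, max_iter=2000, tol=1e-12)
    ours = model.penalized_nll(x, y.astype(float))

    z = (x - x.mean(axis=0)) / x.std(axis=0)
    sk = LogisticRegression(C=1.0 / l2, solver="lbfgs", tol=1e-12,
                            max_iter=5000)
    sk.fit(z, y)
    margins = (z @ sk.coef_[0] + sk.intercept_[0]) * (2 * y - 1)
    sk_loss = np.logaddexp(0.0, -margins).sum() + 0.5 * l2 * sk.coef_[0] @ sk.coef_[0]
    assert ours == pytest.approx(sk_loss, abs=1e-6)


def test_tiny_four_row_table_loss_vs_reference():
    from sklearn.linear_model import LogisticRegression

    x = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 3.0], [3.0, 2.0]])
    y = np.array([0, 0, 1, 1])
    table = _table(x, y.tolist())
    model = fit_logistic(table, l2=1.0, max_iter=2000, tol=1e-12)
    ours = model.penalized_nll(x, y.astype(float))
    z = (x - x.mean(axis=0)) / x.std(axis=0)
    sk = LogisticRegression(C=1.0, solver="lbfgs", tol=1e-12, max_iter=5000)
    sk.fit(z, y)
    margins = (z @ sk.coef_[0] + sk.intercept_[0]) * (2 * y - 1)
    sk_loss = np.logaddexp(0.0, -margins).sum() + 0.5 * sk.coef_[0] @ sk.coef_[0]
    assert ours == pytest.approx(sk_loss, abs=1e-6)


def test_training_deterministic():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(30, 2))
    y = (x[:, 0] > 0).astype(int).tolist()
    m1 = fit_logistic(_table(x, y), l2=0.5)
    m2 = fit_logistic(_table(x, y), l2=0.5)
    assert np.array_equal(m1.weights, m2.weights)
    assert m1.bias == m2.bias
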