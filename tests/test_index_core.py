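import datetime

import pytest

from pubrank.corpus_io import DocumentRecord, JudgmentSet, TopicRecord
from pubrank.fixtures import SyntheticSpec, generate
from pubrank.index_core import (ConfigurationError, IndexConfig, build_index,
                                fit_params, load_index, make_query_plan,
                                save_index, search)
from pubrank.text_pipeline import SynonymTable
from pubrank.weighting import BM25Params, default_params

from _oracles import brute_force_scores

CUTOFF = datetime.date(2019, 12, 1)


# ---------------------------------------------------------------------------
# index statistics
# ---------------------------------------------------------------------------


def test_title_field_statistics_by_hand():
    corpus = [DocumentRecord("d1", title="covid test"),
              DocumentRecord("d2", title="covid")]
    index = build_index(corpus)
    title = index.fields["title"]
    assert title.doc_freq("covid") == 2
    assert title.coll_freq("covid") == 2
    assert title.avg_len == pytest.approx(1.5)
    assert title.tf("covid", "d1") == 1


def test_single_doc_avg_len():
    corpus = [DocumentRecord("only", title="a1 b2 c3")]
    index = build_index(corpus)
    assert index.fields["title"].avg_len == 3.0


def test_absent_term_has_zero_df():
    corpus = [DocumentRecord("d", title="x1")]
    index = build_index(corpus)
    assert index.fields["title"].doc_freq("unseen9") == 0
    assert index.fields["title"].coll_freq("unseen9") == 0


def test_invariant_cf_equals_posting_sum(synth_collection):
    corpus, _, _ = synth_collection
    index = build_index(corpus, IndexConfig(kind="fulltext"))
    for name, stats in index.fields.items():
        for term, plist in stats.postings.items():
            assert stats.coll_freq(term) == sum(plist.values())
            assert stats.doc_freq(term) == len(plist) <= stats.n_docs
        assert stats.avg_len == pytest.approx(
            sum(stats.doc_len.values()) / stats.n_docs)


def test_empty_corpus_rejected():
    with pytest.raises(ConfigurationError):
        build_index([])


def test_whole_section_concatenates_title_then_body():
    doc = DocumentRecord("d", title="alpha9", abstract="beta8 gamma7",
                         full_text="delta6")
    meta = build_index([doc])
    full = build_index([doc], IndexConfig(kind="fulltext"))
    assert meta.fields["whole"].doc_len["d"] == 3
    assert full.fields["whole"].doc_len["d"] == 4
    assert full.fields["abstract"].tf("delta6", "d") == 1
    assert meta.fields["abstract"].tf("delta6", "d") == 0


def test_index_round_trip_on_disk(tmp_path, tiny_corpus):
    index = build_index(tiny_corpus, IndexConfig(kind="fulltext"))
    path = tmp_path / "idx.json"
    save_index(index, path)
    back = load_index(path)
    assert back.kind == index.kind
    assert back.dates == index.dates
    for name in index.fields:
        assert back.fields[name].postings == index.fields[name].postings
        assert back.fields[name].doc_len == index.fields[name].doc_len


# ---------------------------------------------------------------------------
# combinatorial query plan
# ---------------------------------------------------------------------------


def test_query_plan_has_exactly_seven_specs(tiny_topic):
    plan = make_query_plan(tiny_topic)
    assert len(plan) == 7
    combos = {(s.source, s.target) for s in plan}
    assert combos == {
        ("query", "title"), ("query", "abstract"),
        ("question", "title"), ("question", "abstract"),
        ("narrative", "title"), ("narrative", "abstract"),
        ("all", "whole"),
    }


def test_query_plan_empty_field_still_seven_specs():
    topic = TopicRecord(number=2, query="covid", question="", narrative="")
    plan = make_query_plan(topic)
    assert len(plan) == 7
    narrative_specs = [s for s in plan if s.source == "narrative"]
    assert all(s.terms == () for s in narrative_specs)


def test_concatenated_spec_is_field_concatenation(tiny_topic):
    from pubrank.text_pipeline import normalize
    plan = make_query_plan(tiny_topic)
    (concat,) = [s for s in plan if s.source == "all"]
    expected = (normalize(tiny_topic.query) + normalize(tiny_topic.question)
                + normalize(tiny_topic.narrative))
    assert list(concat.terms) == expected


def test_query_plan_synonym_expansion(tiny_topic):
    table = SynonymTable([["covid", "sars-cov-2"]])
    plan = make_query_plan(tiny_topic, synonyms=table)
    (qspec,) = [s for s in plan if (s.source, s.target) == ("query", "title")]
    assert list(qspec.terms) == ["covid", "sars-cov-2", "vaccin"]


# ---------------------------------------------------------------------------
# search semantics
# ---------------------------------------------------------------------------


def test_single_doc_match_at_rank_one():
    corpus = [DocumentRecord("solo", title="covid study")]
    index = build_index(corpus)
    topic = TopicRecord(number=1, query="covid", question="covid",
                        narrative="covid")
    run = search(index, make_query_plan(topic), "bm25", BM25Params(), top_k=10)
    assert run.doc_ids() == ["solo"]
    assert run.entries[0].rank == 1


def test_date_filter_boundary_semantics(tiny_corpus, tiny_topic):
    index = build_index(tiny_corpus)
    plan = make_query_plan(tiny_topic)
    unfiltered = search(index, plan, "bm25", BM25Params(), top_k=10)
    filtered = search(index, plan, "bm25", BM25Params(), top_k=10,
                      cutoff=CUTOFF)
    assert "b" in unfiltered.doc_ids()      # 2019-11-30: before the cutoff
    assert "b" not in filtered.doc_ids()
    assert "c" in filtered.doc_ids()        # 2019-12-01: boundary retained
    assert len(filtered) <= len(unfiltered)


def test_undated_documents_retained_by_default(tiny_topic):
    corpus = [DocumentRecord("undated", title="covid vaccine"),
              DocumentRecord("old", title="covid vaccine",
                             publish_date=datetime.date(2018, 1, 1))]
    index = build_index(corpus)
    plan = make_query_plan(tiny_topic)
    run = search(index, plan, "bm25", BM25Params(), top_k=10, cutoff=CUTOFF)
    assert run.doc_ids() == ["undated"]
    dropped = search(index, plan, "bm25", BM25Params(), top_k=10,
                     cutoff=CUTOFF, keep_undated=False)
    assert dropped.doc_ids() == []


def test_score_ties_broken_by_doc_id():
    corpus = [DocumentRecord("zz", title="covid"),
              DocumentRecord("aa", title="covid")]
    index = build_index(corpus)
    topic = TopicRecord(number=1, query="covid", question="", narrative="")
    run = search(index, make_query_plan(topic), "bm25", BM25Params(), top_k=10)
    assert run.doc_ids() == ["aa", "zz"]


def test_unknown_model_rejected(tiny_corpus, tiny_topic):
    index = build_index(tiny_corpus)
    with pytest.raises(ConfigurationError):
        search(index, make_query_plan(tiny_topic), "tfidf", None)


@pytest.mark.parametrize("model", ["bm25", "dfr", "lmd"])
def test_search_permutation_invariant_in_corpus_order(model, synth_collection):
    corpus, topics, _ = synth_collection
    topic = topics[0]
    params = default_params(model)
    fwd = build_index(corpus)
    rev = build_index(corpus[::-1])
    run_fwd = search(fwd, make_query_plan(topic), model, params, top_k=len(corpus))
    run_rev = search(rev, make_query_plan(topic), model, params, top_k=len(corpus))
    assert run_fwd.doc_ids() == run_rev.doc_ids()
    for a, b in zip(run_fwd.entries, run_rev.entries):
        assert a.score == pytest.approx(b.score, abs=1e-12)


@pytest.mark.parametrize("model", ["bm25", "dfr", "lmd"])
@pytest.mark.parametrize("kind", ["metadata", "fulltext"])
def test_search_matches_brute_force_oracle(model, kind, synth_collection):
    corpus, topics, _ = synth_collection
    index = build_index(corpus, IndexConfig(kind=kind))
    params = default_params(model)
    for topic in topics:
        plan = make_query_plan(topic, kind)
        run = search(index, plan, model, params, top_k=len(corpus))
        expected = brute_force_scores(corpus, plan, model, params, kind)
        got = {e.doc_id: e.score for e in run.entries}
        assert set(got) == {d for d, s in expected.items() if s != 0.0 or model == "lmd"}
        for doc_id, score in got.items():
            assert score == pytest.approx(expected[doc_id], abs=1e-9)


# ---------------------------------------------------------------------------
# cross-validated parameter fitting
# ---------------------------------------------------------------------------


def test_fit_params_grid_of_one(synth_collection):
    corpus, topics, qrels = synth_collection
    index = build_index(corpus)
    only = BM25Params(k1=0.9, b=0.4)
    best = fit_params(index, topics, qrels, "bm25", [only], folds=2)
    assert best == only


def test_fit_params_empty_grid_rejected(synth_collection):
    corpus, topics, qrels = synth_collection
    index = build_index(corpus)
    with pytest.raises(ConfigurationError):
        fit_params(index, topics, qrels, "bm25", [], folds=2)


def test_fit_params_more_folds_than_topics(synth_collection):
    corpus, topics, qrels = synth_collection
    index = build_index(corpus)
    with pytest.raises(ConfigurationError):
        fit_params(index, topics, qrels, "bm25", [BM25Params()], folds=50)


def test_fit_params_recovers_length_normalization():
    """On a corpus where relevant documents are short and long documents
    spuriously repeat the query terms, cross-validated P@10 prefers a
    larger b than 0, and matches exhaustive grid evaluation."""
    from pubrank.evaluation import precision_at_k

    corpus = []
    qrels = JudgmentSet()
    topics = []
    for t in range(1, 7):
        term = f"q{t}x"
        topics.append(TopicRecord(number=t, query=term, question=term,
                                  narrative=term))
        # relevant: concise on-topic doc (term twice in a 5-term abstract)
        corpus.append(DocumentRecord(f"rel-{t}", title=f"title{t}a",
                                     abstract=f"{term} {term} focused report here"))
        qrels.add(t, f"rel-{t}", 2)
        # spurious: long documents that repeat the term but are padding
        for j in range(12):
            stuffing = (f"{term} " * 3) + (f"filler{j}z " * 117)
            corpus.append(DocumentRecord(f"spam-{t}-{j:02d}",
                                         title=f"title{t}b{j}",
                                         abstract=stuffing))
            qrels.add(t, f"spam-{t}-{j:02d}", 0)
    index = build_index(corpus)
    grid = [BM25Params(k1=1.2, b=b) for b in (0.0, 0.5, 1.0)]
    best = fit_params(index, topics, qrels, "bm25", grid, folds=3)
    assert best.b > 0.0

    # oracle: exhaustive evaluation of the same grid without folds
    def mean_p10(params):
        vals = []
        for topic in topics:
            run = search(index, make_query_plan(topic), "bm25", params,
                         top_k=100)
            vals.append(precision_at_k(run, qrels, 10))
        return sum(vals) / len(vals)

    exhaustive_best = max(grid, key=mean_p10)
    assert best.b == exhaustive_best.b
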