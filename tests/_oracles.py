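"""Independent test oracles, deliberately written in a naive style with
no code shared with the package's scoring or evaluation paths."""

import math

from pubrank.text_pipeline import normalize

# ---------------------------------------------------------------------------
# brute-force document-at-a-time retrieval scorer: recomputes every
# collection statistic by direct counting over the raw corpus text and
# applies each weighting formula inline, with no inverted index
# ---------------------------------------------------------------------------


def _section_terms(doc, target, kind):
    title = normalize(doc.title)
    body_text = doc.abstract
    if kind == "fulltext" and doc.full_text:
        body_text = doc.abstract + " " + doc.full_text
    body = normalize(body_text)
    if target == "title":
        return title
    if target == "abstract":
        return body
    if target == "whole":
        return title + body
    raise ValueError(target)


def brute_force_scores(corpus, plan, model, params, kind):
    """doc_id -> summed score over all query specs; docs scoring nothing
    are omitted (except under the language model, which smooths every
    document as soon as one query term exists in the collection)."""
    scores = {}
    for spec in plan:
        terms_by_doc = {d.doc_id: _section_terms(d, spec.target, kind)
                        for d in corpus}
        lengths = {d: len(t) for d, t in terms_by_doc.items()}
        n_docs = len(corpus)
        total = sum(lengths.values())
        avg_len = total / n_docs

        def df(term):
            return sum(1 for t in terms_by_doc.values() if term in t)

        def cf(term):
            return sum(t.count(term) for t in terms_by_doc.values())

        if model == "lmd":
            valid = [t for t in spec.terms if cf(t) > 0]
            if not valid:
                continue
            for doc in corpus:
                tl = terms_by_doc[doc.doc_id]
                s = 0.0
                for term in valid:
                    p_coll = cf(term) / total
                    s += math.log((tl.count(term) + params.mu * p_coll)
                                  / (lengths[doc.doc_id] + params.mu))
                scores[doc.doc_id] = scores.get(doc.doc_id, 0.0) + s
        else:
            for term in spec.terms:
                n_t = df(term)
                c_t = cf(term)
                if n_t == 0:
                    continue
                for doc in corpus:
                    tf = terms_by_doc[doc.doc_id].count(term)
                    if tf == 0:
                        continue
                    dl = lengths[doc.doc_id]
                    if model == "bm25":
                        idf = math.log(1 + (n_docs - n_t + 0.5) / (n_t + 0.5))
                        w = idf * tf * (params.k1 + 1) / (
                            tf + params.k1 * (1 - params.b + params.b * dl / avg_len))
                    elif model == "dfr":
                        lam = c_t / n_docs
                        tfn = tf * math.log2(1 + avg_len / dl) if dl else tf
                        w = params.k * (math.log2(1 + lam)
                                        + tfn * math.log2((1 + lam) / lam))
                    else:
                        raise ValueError(model)
                    scores[doc.doc_id] = scores.get(doc.doc_id, 0.0) + w
    return scores


# ---------------------------------------------------------------------------
# naive graded-relevance evaluator (trec_eval conventions)
# ---------------------------------------------------------------------------


def ref_precision_at_k(ranked_doc_ids, grades, k):
    hits = 0
    for doc in ranked_doc_ids[:k]:
        if grades.get(doc, 0) >= 1:
            hits += 1
    return hits / k


def ref_ndcg_at_k(ranked_doc_ids, grades, k):
    dcg = 0.0
    for i, doc in enumerate(ranked_doc_ids[:k]):
        dcg += grades.get(doc, 0) / math.log2(i + 2)
    ideal = sorted(grades.values(), reverse=True)[:k]
    idcg = 0.0
    for i, g in enumerate(ideal):
        idcg += g / math.log2(i + 2)
    if idcg == 0:
        return 0.0
    return dcg / idcg


def ref_average_precision(ranked_doc_ids, grades):
    n_rel = sum(1 for g in grades.values() if g >= 1)
    if n_rel == 0:
        return 0.0
    found = 0
    acc = 0.0
    for i, doc in enumerate(ranked_doc_ids, start=1):
        if grades.get(doc, 0) >= 1:
            found += 1
            acc += found / i
    return acc / n_rel


def ref_bpref(ranked_doc_ids, grades):
    n_rel = sum(1 for g in grades.values() if g >= 1)
    n_nonrel = sum(1 for g in grades.values() if g == 0)
    if n_rel == 0:
        return 0.0
    if n_nonrel == 0:
        found = sum(1 for doc in ranked_doc_ids if grades.get(doc, 0) >= 1)
        return found / n_rel
    acc = 0.0
    nonrel_seen = 0
    for doc in ranked_doc_ids:
        if doc not in grades:
            continue
        if grades[doc] >= 1:
            acc += 1.0 - min(nonrel_seen, n_rel) / min(n_rel, n_nonrel)
        else:
            nonrel_seen += 1
    return acc / n_rel
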