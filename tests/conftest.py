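import datetime

import pytest

from pubrank.corpus_io import DocumentRecord, JudgmentSet, TopicRecord
from pubrank.fixtures import SyntheticSpec, generate


@pytest.fixture(scope="session")
def synth_collection():
    """Default synthetic collection: 3 themes x 20 docs, pooled judging."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture()
def tiny_corpus():
    return [
        DocumentRecord("a", title="covid test", abstract="viral spread study",
                       publish_date=datetime.date(2020, 3, 1), source="x"),
        DocumentRecord("b", title="covid", abstract="lung imaging",
                       publish_date=datetime.date(2019, 11, 30), source="x"),
        DocumentRecord("c", title="influenza season",
                       abstract="covid vaccine trial results",
                       full_text="extended discussion of covid vaccine trials",
                       publish_date=datetime.date(2019, 12, 1), source="y"),
    ]


@pytest.fixture()
def tiny_topic():
    return TopicRecord(number=1, query="covid vaccine",
                       question="what covid vaccines are in trials?",
                       narrative="reports on covid vaccine trials and results")


@pytest.fixture()
def tiny_qrels():
    q = JudgmentSet()
    q.add(1, "a", 1)
    q.add(1, "b", 0)
    q.add(1, "c", 2)
    return q
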