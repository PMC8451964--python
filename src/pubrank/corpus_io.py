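"""Readers and writers for the four exchange formats of the toolkit.

Four kinds of artifact move between stages of a literature-retrieval
experiment:

* a **corpus** of publication records (id, title, abstract, optional full
  text, publication date, source label), in CORD-19-metadata style;
* a **topic set**: information needs with three free-text fields
  (``query``, ``question``, ``narrative``) in TREC XML;
* **qrels**: graded relevance judgments, 0 = irrelevant, 1 = somewhat
  relevant, 2 = highly relevant, in the 4-column TREC format;
* **runs**: per-topic ranked answer lists in the 6-column
  ``topic Q0 docid rank score tag`` TREC format.

All readers validate strictly (duplicate ids, bad grades, non-consecutive
ranks raise) except for publication dates, which are parsed leniently:
heterogeneous metadata exports mix full dates, year-month and bare years,
so ``2020`` becomes 2020-01-01 and ``2020-03`` becomes 2020-03-01; an
unparseable date is stored as absent rather than failing the row.
"""

from __future__ import annotations

import csv
import datetime
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from lxml import etree

__all__ = [
    "DocumentRecord",
    "TopicRecord",
    "JudgmentSet",
    "RankedList",
    "RunEntry",
    "FormatError",
    "IntegrityError",
    "parse_date_lenient",
    "read_corpus",
    "write_corpus",
    "read_topics",
    "write_topics",
    "read_qrels",
    "write_qrels",
    "read_run",
    "write_run",
]

CORPUS_COLUMNS = ("doc_id", "title", "abstract", "full_text", "publish_date", "source")
REQUIRED_COLUMNS = ("doc_id", "title", "abstract")

#: decimal places used when serializing run scores; enough for a lossless
#: round-trip of rank-deciding differences at fixture scale.
SCORE_DECIMALS = 6

DEFAULT_RUN_DEPTH = 1000


class FormatError(ValueError):
    """A file does not conform to its declared layout."""


class IntegrityError(ValueError):
    """Content violates a uniqueness or consistency invariant."""


@dataclass(frozen=True)
class DocumentRecord:
    """One publication: sectioned text plus metadata.

    ``title`` and ``abstract`` are always strings (possibly empty);
    ``full_text`` and ``publish_date`` may be absent.
    """

    doc_id: str
    title: str = ""
    abstract: str = ""
    full_text: str | None = None
    publish_date: datetime.date | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise IntegrityError("doc_id must be nonempty")


@dataclass(frozen=True)
class TopicRecord:
    """A three-field information need (TREC-COVID topic style)."""

    number: int
    query: str = ""
    question: str = ""
    narrative: str = ""

    def __post_init__(self) -> None:
        if self.number <= 0:
            raise IntegrityError(f"topic number must be positive, got {self.number}")


class JudgmentSet:
    """Graded relevance judgments: (topic, doc_id) -> grade in {0, 1, 2}."""

    GRADES = frozenset({0, 1, 2})

    def __init__(self, judgments: Mapping[tuple[int, str], int] | None = None):
        self._grades: dict[tuple[int, str], int] = {}
        if judgments:
            for (topic, doc_id), grade in judgments.items():
                self.add(topic, doc_id, grade)

    def add(self, topic: int, doc_id: str, grade: int) -> None:
        if grade not in self.GRADES:
            raise FormatError(f"grade must be 0, 1 or 2, got {grade!r}")
        key = (topic, doc_id)
        if key in self._grades:
            raise IntegrityError(f"duplicate judgment for topic {topic}, doc {doc_id!r}")
        self._grades[key] = grade

    def grade(self, topic: int, doc_id: str) -> int | None:
        """Grade for the pair, or None when the pair is unjudged."""
        return self._grades.get((topic, doc_id))

    def is_relevant(self, topic: int, doc_id: str) -> bool:
        """Binary relevance: grade >= 1."""
        return self._grades.get((topic, doc_id), 0) >= 1

    def topics(self) -> list[int]:
        return sorted({t for t, _ in self._grades})

    def judged_docs(self, topic: int) -> dict[str, int]:
        """doc_id -> grade for every judged document of ``topic``."""
        return {d: g for (t, d), g in self._grades.items() if t == topic}

    def items(self) -> Iterator[tuple[tuple[int, str], int]]:
        return iter(self._grades.items())

    def __len__(self) -> int:
        return len(self._grades)

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self._grades

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, JudgmentSet):
            return NotImplemented
        return self._grades == other._grades


@dataclass(frozen=True)
class RunEntry:
    doc_id: str
    score: float
    rank: int


class RankedList:
    """An ordered, scored answer list for one topic.

    Invariants enforced at construction: ranks are 1..n consecutive,
    scores non-increasing with rank, doc_ids unique.
    """

    def __init__(
        self,
        topic: int,
        entries: Iterable[RunEntry | tuple[str, float, int]],
        tag: str = "run",
    ):
        self.topic = int(topic)
        self.tag = tag
        self.entries: list[RunEntry] = [
            e if isinstance(e, RunEntry) else RunEntry(*e) for e in entries
        ]
        self._validate()

    @classmethod
    def from_scores(cls, topic: int, scores: Mapping[str, float], tag: str = "run",
                    top_k: int | None = None) -> "RankedList":
        """Rank a doc_id -> score map: score descending, doc_id ascending on ties."""
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        if top_k is not None:
            ordered = ordered[:top_k]
        return cls(topic, [RunEntry(d, s, i + 1) for i, (d, s) in enumerate(ordered)], tag)

    def _validate(self) -> None:
        seen: set[str] = set()
        prev_score = None
        for i, e in enumerate(self.entries):
            if e.rank != i + 1:
                raise FormatError(
                    f"topic {self.topic}: ranks must be consecutive from 1, "
                    f"got {e.rank} at position {i + 1}"
                )
            if e.doc_id in seen:
                raise IntegrityError(f"topic {self.topic}: duplicate doc_id {e.doc_id!r}")
            seen.add(e.doc_id)
            if prev_score is not None and e.score > prev_score + 1e-12:
                raise FormatError(
                    f"topic {self.topic}: scores must be non-increasing with rank"
                )
            prev_score = e.score
        self._ranks = {e.doc_id: e.rank for e in self.entries}

    def rank_of(self, doc_id: str) -> int | None:
        return self._ranks.get(doc_id)

    def doc_ids(self) -> list[str]:
        return [e.doc_id for e in self.entries]

    def truncated(self, depth: int) -> "RankedList":
        return RankedList(self.topic, self.entries[:depth], self.tag)

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RankedList):
            return NotImplemented
        return self.topic == other.topic and self.entries == other.entries

    def __repr__(self) -> str:
        return f"RankedList(topic={self.topic}, n={len(self.entries)}, tag={self.tag!r})"


_DATE_PATTERNS = (
    (re.compile(r"^(\d{4})-(\d{2})-(\d{2})$"), ("y", "m", "d")),
    (re.compile(r"^(\d{4})-(\d{1,2})$"), ("y", "m")),
    (re.compile(r"^(\d{4})$"), ("y",)),
)


def parse_date_lenient(text: str | None) -> datetime.date | None:
    """Parse a heterogeneous date string into the most specific date available.

    Year-only -> Jan 1 of that year; year-month -> first of the month;
    full ISO date kept as-is; anything else (including impossible dates)
    -> None.
    """
    if text is None:
        return None
    text = text.strip()
    if not text:
        return None
    for pattern, parts in _DATE_PATTERNS:
        m = pattern.match(text)
        if m is None:
            continue
        vals = dict(zip(parts, (int(g) for g in m.groups())))
        try:
            return datetime.date(vals["y"], vals.get("m", 1), vals.get("d", 1))
        except ValueError:
            return None
    return None


def _record_from_row(row: Mapping[str, str], line_no: int) -> DocumentRecord:
    doc_id = (row.get("doc_id") or "").strip()
    if not doc_id:
        raise FormatError(f"line {line_no}: empty doc_id")
    full_text = row.get("full_text")
    if full_text is not None and full_text == "":
        full_text = None
    return DocumentRecord(
        doc_id=doc_id,
        title=row.get("title") or "",
        abstract=row.get("abstract") or "",
        full_text=full_text,
        publish_date=parse_date_lenient(row.get("publish_date")),
        source=row.get("source") or "",
    )


def read_corpus(path: str | Path, dialect: str = "csv") -> list[DocumentRecord]:
    """Read a corpus file into DocumentRecords, preserving row order.

    Dialects: ``"csv"`` / ``"tsv"`` — delimited with a header naming at
    least doc_id, title, abstract; ``"jsonl"`` — one JSON object per line
    with the same keys.  Duplicate doc_ids raise IntegrityError.
    """
    path = Path(path)
    records: list[DocumentRecord] = []
    seen: set[str] = set()

    if dialect in ("csv", "tsv"):
        delim = "," if dialect == "csv" else "\t"
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh, delimiter=delim)
            if reader.fieldnames is None:
                raise FormatError(f"{path}: empty corpus file")
            missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
            if missing:
                raise FormatError(f"{path}: missing required columns {missing}")
            for i, row in enumerate(reader, start=2):
                records.append(_record_from_row(row, i))
    elif dialect == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for i, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise FormatError(f"{path} line {i}: invalid JSON ({exc})") from exc
                missing = [c for c in REQUIRED_COLUMNS if c not in obj]
                if missing:
                    raise FormatError(f"{path} line {i}: missing keys {missing}")
                records.append(_record_from_row(obj, i))
    else:
        raise FormatError(f"unknown corpus dialect {dialect!r}")

    for rec in records:
        if rec.doc_id in seen:
            raise IntegrityError(f"duplicate doc_id {rec.doc_id!r}")
        seen.add(rec.doc_id)
    return records


def write_corpus(records: Sequence[DocumentRecord], path: str | Path,
                 dialect: str = "csv") -> None:
    """Write records in a layout ``read_corpus`` accepts losslessly."""
    path = Path(path)
    if dialect in ("csv", "tsv"):
        delim = "," if dialect == "csv" else "\t"
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(CORPUS_COLUMNS), delimiter=delim)
            writer.writeheader()
            for rec in records:
                writer.writerow({
                    "doc_id": rec.doc_id,
                    "title": rec.title,
                    "abstract": rec.abstract,
                    "full_text": rec.full_text or "",
                    "publish_date": rec.publish_date.isoformat() if rec.publish_date else "",
                    "source": rec.source,
                })
    elif dialect == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps({
                    "doc_id": rec.doc_id,
                    "title": rec.title,
                    "abstract": rec.abstract,
                    "full_text": rec.full_text,
                    "publish_date": rec.publish_date.isoformat() if rec.publish_date else None,
                    "source": rec.source,
                }, sort_keys=True) + "\n")
    else:
        raise FormatError(f"unknown corpus dialect {dialect!r}")


def read_topics(path: str | Path) -> list[TopicRecord]:
    """Parse a TREC-COVID topic XML file.

    Layout: ``<topics><topic number="N"><query/><question/><narrative/>
    </topic>...</topics>``.  Field text is whitespace-trimmed; a missing
    field element raises FormatError naming the topic.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"{path}: malformed XML ({exc})") from exc
    topics: list[TopicRecord] = []
    for el in tree.getroot().iter("topic"):
        number_attr = el.get("number")
        if number_attr is None:
            raise FormatError(f"{path}: topic element without number attribute")
        number = int(number_attr)
        fields = {}
        for name in ("query", "question", "narrative"):
            child = el.find(name)
            if child is None:
                raise FormatError(f"{path}: topic {number} missing <{name}> element")
            fields[name] = (child.text or "").strip()
        topics.append(TopicRecord(number=number, **fields))
    numbers = [t.number for t in topics]
    if len(set(numbers)) != len(numbers):
        raise IntegrityError(f"{path}: duplicate topic numbers")
    return topics


def write_topics(topics: Sequence[TopicRecord], path: str | Path) -> None:
    root = etree.Element("topics")
    for t in topics:
        el = etree.SubElement(root, "topic", number=str(t.number))
        for name in ("query", "question", "narrative"):
            etree.SubElement(el, name).text = getattr(t, name)
    Path(path).write_bytes(etree.tostring(root, pretty_print=True,
                                          xml_declaration=True, encoding="utf-8"))


def read_qrels(path: str | Path) -> JudgmentSet:
    """Read a 4-column TREC qrels file: ``topic iteration doc grade``."""
    path = Path(path)
    judgments = JudgmentSet()
    with path.open(encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path} line {i}: expected 4 fields, got {len(parts)}")
            topic_s, _iteration, doc_id, grade_s = parts
            try:
                topic, grade = int(topic_s), int(grade_s)
            except ValueError as exc:
                raise FormatError(f"{path} line {i}: non-integer topic or grade") from exc
            if grade not in JudgmentSet.GRADES:
                raise FormatError(f"{path} line {i}: grade {grade} outside {{0,1,2}}")
            judgments.add(topic, doc_id, grade)
    return judgments


def write_qrels(judgments: JudgmentSet, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for (topic, doc_id), grade in sorted(judgments.items()):
            fh.write(f"{topic} 0 {doc_id} {grade}\n")


def write_run(lists: Sequence[RankedList], path: str | Path,
              depth: int = DEFAULT_RUN_DEPTH) -> None:
    """Write ranked lists in the TREC 6-column run format.

    Each list is truncated to ``depth`` entries; scores printed with
    SCORE_DECIMALS decimal places so read_run(write_run(x)) reproduces x
    to that precision.
    """
    with Path(path).open("w", encoding="utf-8") as fh:
        for lst in sorted(lists, key=lambda l: l.topic):
            for e in lst.entries[:depth]:
                fh.write(f"{lst.topic} Q0 {e.doc_id} {e.rank} "
                         f"{e.score:.{SCORE_DECIMALS}f} {lst.tag}\n")


def read_run(path: str | Path) -> list[RankedList]:
    """Read a TREC run file back into RankedLists (one per topic)."""
    path = Path(path)
    by_topic: dict[int, list[RunEntry]] = {}
    tags: dict[int, str] = {}
    with path.open(encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise FormatError(f"{path} line {i}: expected 6 fields, got {len(parts)}")
            topic_s, q0, doc_id, rank_s, score_s, tag = parts
            if q0 != "Q0":
                raise FormatError(f"{path} line {i}: second field must be Q0")
            try:
                topic, rank, score = int(topic_s), int(rank_s), float(score_s)
            except ValueError as exc:
                raise FormatError(f"{path} line {i}: bad numeric field") from exc
            by_topic.setdefault(topic, []).append(RunEntry(doc_id, score, rank))
            tags[topic] = tag
    lists = []
    for topic in sorted(by_topic):
        entries = sorted(by_topic[topic], key=lambda e: e.rank)
        lists.append(RankedList(topic, entries, tags[topic]))  # validates ranks
    return lists
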