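"""Text normalization and synonym expansion.

Documents (at indexing time) and topics (at search time) pass through the
same deterministic pipeline: lower-casing, removal of every character
outside ``[a-z0-9-]`` (replaced by whitespace), whitespace tokenization,
and Porter stemming.  Stemming is applied only to purely alphabetic
tokens, so domain terms carrying digits or hyphens ("covid-19",
"sars-cov-2") survive intact.  There is no stopword removal.

Query expansion appends, after each query term that triggers an entry in
a small synonym table, the other members of its synonym group.  The table
is applied to queries only, never at indexing time, and ships seeded with
a minimal COVID cluster (editable plain-text config, one comma-separated
group per line).
"""

from __future__ import annotations

import re
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

from ._porter import porter_stem

__all__ = ["normalize", "SynonymTable", "expand", "load_synonyms", "default_synonyms"]

_STRIP_RE = re.compile(r"[^a-z0-9-]+")
_ALPHA_RE = re.compile(r"^[a-z]+$")


def normalize(text: str) -> list[str]:
    """Normalize raw text into index/search terms.

    Total function: empty or symbol-only input yields an empty list.
    Tokens consisting solely of "-" are dropped as degenerate.
    """
    cleaned = _STRIP_RE.sub(" ", text.lower())
    terms = []
    for token in cleaned.split():
        if not token.strip("-"):
            continue
        if _ALPHA_RE.match(token):
            token = porter_stem(token)
        terms.append(token)
    return terms


class SynonymTable:
    """Map term -> ordered tuple of equivalent terms (both sides normalized)."""

    def __init__(self, groups: Iterable[Iterable[str]] = ()):
        self._table: dict[str, tuple[str, ...]] = {}
        for group in groups:
            self.add_group(group)

    def add_group(self, group: Iterable[str]) -> None:
        """Register a synonym group; every member triggers the others."""
        members: list[str] = []
        for raw in group:
            for term in normalize(raw):
                if term not in members:
                    members.append(term)
        for term in members:
            others = tuple(t for t in members if t != term)
            existing = self._table.get(term, ())
            merged = existing + tuple(t for t in others if t not in existing)
            if merged:
                self._table[term] = merged

    def synonyms_of(self, term: str) -> tuple[str, ...]:
        return self._table.get(term, ())

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, term: str) -> bool:
        return term in self._table

    def as_dict(self) -> dict[str, tuple[str, ...]]:
        return dict(self._table)


def expand(terms: Iterable[str], table: SynonymTable) -> list[str]:
    """Append each trigger term's synonyms once, directly after it.

    Never removes terms; duplicates in the input are each expanded
    (multiset semantics).
    """
    out: list[str] = []
    for term in terms:
        out.append(term)
        out.extend(table.synonyms_of(term))
    return out


def load_synonyms(path: str | Path) -> SynonymTable:
    """Load a synonym table from plain text: one comma-separated group per
    line; blank lines and lines starting with ``#`` ignored."""
    table = SynonymTable()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        table.add_group(part.strip() for part in line.split(",") if part.strip())
    return table


def default_synonyms() -> SynonymTable:
    """The shipped minimal COVID-cluster synonym table."""
    text = resources.files("pubrank").joinpath("data/synonyms.txt").read_text("utf-8")
    table = SynonymTable()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        table.add_group(part.strip() for part in line.split(",") if part.strip())
    return table
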