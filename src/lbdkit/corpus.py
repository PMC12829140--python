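"""Abstract corpora and boolean term queries.

The unit of retrieval is a title+abstract document (a PubMed-like record).
Term queries are disjunctions of conjunctions of exact phrases: ``|`` joins
alternatives at the outer level and ``&`` binds tighter, so
``breast cancer&EGFR|HER2`` means (``breast cancer`` AND ``EGFR``) OR
``HER2``.

Matching semantics: a phrase matches a document iff it occurs as a
contiguous, case-insensitive substring of ``title + " " + text`` delimited
by token boundaries, where a boundary is any non-alphanumeric character or
the string edge. Hyphens therefore count as boundaries: the phrase ``AHR``
matches "the AHR-dependent pathway" but not "SAHRA". No stemming or synonym
expansion is performed beyond explicit ``|`` alternatives.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

__all__ = [
    "AbstractRecord",
    "Corpus",
    "TermQuery",
    "CorpusError",
    "QueryError",
    "read_corpus",
    "write_corpus_jsonl",
    "read_term_list",
    "parse_query",
    "match_documents",
    "phrase_matches_text",
]


class CorpusError(ValueError):
    """Raised for malformed corpus files or records."""


class QueryError(ValueError):
    """Raised for malformed term queries."""


@dataclass(frozen=True)
class AbstractRecord:
    """One document: a PMID-like id, title, abstract body and optional year."""

    doc_id: str
    title: str = ""
    text: str = ""
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("doc_id must be non-empty")
        if self.title is None or self.text is None:
            raise CorpusError(f"record {self.doc_id}: title/text may be empty but not absent")

    @property
    def combined_text(self) -> str:
        return f"{self.title} {self.text}"


class Corpus:
    """An ordered collection of AbstractRecords with unique doc_ids.

    Lower-cased combined texts are cached once per corpus, and per-phrase
    match sets are memoized, giving a simple phrase -> documents index.
    """

    def __init__(self, records: Iterable[AbstractRecord]):
        self.records: list[AbstractRecord] = list(records)
        self._by_id: dict[str, AbstractRecord] = {}
        for rec in self.records:
            if rec.doc_id in self._by_id:
                raise CorpusError(f"duplicate doc_id: {rec.doc_id}")
            self._by_id[rec.doc_id] = rec
        self._lower_texts: Optional[list[str]] = None
        self._phrase_cache: dict[str, frozenset[str]] = {}

    @property
    def N(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._by_id

    def __getitem__(self, doc_id: str) -> AbstractRecord:
        return self._by_id[doc_id]

    @property
    def doc_ids(self) -> frozenset[str]:
        return frozenset(self._by_id)

    def _lowered(self) -> list[str]:
        if self._lower_texts is None:
            self._lower_texts = [rec.combined_text.lower() for rec in self.records]
        return self._lower_texts

    def match_phrase(self, phrase: str) -> frozenset[str]:
        """All doc_ids whose title+text contain the phrase at token boundaries."""
        key = phrase.lower()
        cached = self._phrase_cache.get(key)
        if cached is not None:
            return cached
        pattern = _phrase_pattern(phrase)
        hits = frozenset(
            rec.doc_id
            for rec, low in zip(self.records, self._lowered())
            if pattern.search(low)
        )
        self._phrase_cache[key] = hits
        return hits


@dataclass(frozen=True)
class TermQuery:
    """A parsed boolean query: outer ``|`` alternatives of inner ``&`` phrases."""

    raw: str
    alternatives: tuple[tuple[str, ...], ...]

    def __str__(self) -> str:
        return "|".join("&".join(alt) for alt in self.alternatives)

    @property
    def surface_form(self) -> str:
        """Display form: the first phrase of the first alternative."""
        return self.alternatives[0][0]


# --- reading / writing -------------------------------------------------------

def read_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Load a corpus from a JSONL or MEDLINE-tagged file.

    JSONL dialect: UTF-8, one object per line with keys ``doc_id`` (str),
    ``title`` (str), ``text`` (str) and optional ``year`` (int). MEDLINE
    records map PMID -> doc_id, TI -> title, AB -> text, DP year -> year.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusError(f"corpus file not found: {path}")
    if format == "jsonl":
        records = list(_read_jsonl(path))
    elif format == "medline":
        records = list(_read_medline(path))
    else:
        raise CorpusError(f"unknown corpus format: {format!r}")
    for rec in records:
        if not rec.title and not rec.text:
            logger.warning("record %s has empty title and text; retained", rec.doc_id)
    return Corpus(records)


def _read_jsonl(path: Path) -> Iterable[AbstractRecord]:
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: unparseable JSON: {exc}") from exc
            if not isinstance(obj, dict) or "doc_id" not in obj:
                raise CorpusError(f"{path}:{lineno}: record missing doc_id")
            year = obj.get("year")
            yield AbstractRecord(
                doc_id=str(obj["doc_id"]),
                title=obj.get("title", ""),
                text=obj.get("text", ""),
                year=int(year) if year is not None else None,
            )


def _read_medline(path: Path) -> Iterable[AbstractRecord]:
    from Bio import Medline  # standard tagged-format parser

    with path.open(encoding="utf-8") as fh:
        for i, rec in enumerate(Medline.parse(fh), start=1):
            pmid = rec.get("PMID")
            if not pmid:
                raise CorpusError(f"{path}: MEDLINE record {i} lacks a PMID field")
            dp = rec.get("DP", "")
            m = re.search(r"\b(\d{4})\b", dp)
            yield AbstractRecord(
                doc_id=str(pmid),
                title=rec.get("TI", ""),
                text=rec.get("AB", ""),
                year=int(m.group(1)) if m else None,
            )


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for rec in corpus:
            obj = {"doc_id": rec.doc_id, "title": rec.title, "text": rec.text}
            if rec.year is not None:
                obj["year"] = rec.year
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


def read_term_list(path: str | Path) -> list[TermQuery]:
    """Read a term-list file: one query per line, ``#`` comment lines ignored."""
    queries = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        queries.append(parse_query(line))
    return queries


# --- query parsing -----------------------------------------------------------

def parse_query(raw: str) -> TermQuery:
    """Parse a boolean term query. ``|`` splits alternatives, ``&`` binds tighter.

    No parentheses are supported; phrase whitespace is trimmed but phrase
    text is otherwise preserved verbatim.
    """
    if raw is None or not raw.strip():
        raise QueryError("empty query")
    alternatives = []
    for alt in raw.split("|"):
        phrases = tuple(p.strip() for p in alt.split("&"))
        if any(not p for p in phrases):
            raise QueryError(f"empty phrase in query: {raw!r}")
        alternatives.append(phrases)
    return TermQuery(raw=raw, alternatives=tuple(alternatives))


# --- matching ----------------------------------------------------------------

def _phrase_pattern(phrase: str) -> re.Pattern:
    # Token boundary = non-alphanumeric or string edge; hyphens are boundaries.
    return re.compile(
        r"(?<![0-9a-z])" + re.escape(phrase.lower()) + r"(?![0-9a-z])"
    )


def phrase_matches_text(phrase: str, text: str) -> bool:
    """True iff phrase occurs in text case-insensitively at token boundaries."""
    return bool(_phrase_pattern(phrase).search(text.lower()))


def query_matches_record(query: TermQuery, record: AbstractRecord) -> bool:
    """Naive per-document evaluation of the boolean expression."""
    text = record.combined_text
    return any(
        all(phrase_matches_text(p, text) for p in alt) for alt in query.alternatives
    )


def match_documents(
    query: TermQuery, corpus: Corpus, cutoff_year: Optional[int] = None
) -> frozenset[str]:
    """Evaluate a query against a corpus; returns the matching doc_id set.

    Documents with ``year > cutoff_year`` are excluded when a cutoff is given
    (time-slicing at year granularity); documents without a year are kept.
    """
    result: set[str] = set()
    for alt in query.alternatives:
        alt_hits: Optional[frozenset[str]] = None
        for phrase in alt:
            hits = corpus.match_phrase(phrase)
            alt_hits = hits if alt_hits is None else alt_hits & hits
            if not alt_hits:
                break
        if alt_hits:
            result |= alt_hits
    if cutoff_year is not None:
        result = {
            d for d in result
            if corpus[d].year is None or corpus[d].year <= cutoff_year
        }
    return frozenset(result)
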