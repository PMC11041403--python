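"""Reading, validating and preprocessing dated abstract records.

Supported dialects are MEDLINE/PubMed XML, 4-column TSV and JSON-lines.
Records missing a date or an abstract are skipped (and counted); everything
else is streamed through unchanged.  Preprocessing lowercases, strips
characters outside ``[a-z]``/``-`` and merges multiword phrases into single
``+``-joined tokens before tokenization.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .errors import ConfigurationError, CorpusFormatError

__all__ = [
    "DocumentRecord",
    "TokenizedDocument",
    "CorpusReader",
    "read_corpus",
    "preprocess",
    "tokenize_text",
    "filter_span",
    "load_merge_list",
]

TOKEN_RE = re.compile(r"[a-z]+([-+][a-z]+)*\Z")

_MONTH_NAMES = {
    name.lower(): i + 1
    for i, name in enumerate(
        ["Jan", "Feb", "Mar", "Apr", "May", "Jun", "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]
    )
}


@dataclass(frozen=True)
class DocumentRecord:
    """One dated abstract record."""

    doc_id: str
    date: _dt.date
    title: str
    abstract: str


@dataclass(frozen=True)
class TokenizedDocument:
    """A document reduced to its preprocessed token sequence."""

    doc_id: str
    date: _dt.date
    tokens: tuple[str, ...]


def _parse_date(raw: str) -> _dt.date | None:
    """Parse ISO-8601 (full, year-month, or year-only) dates.

    Year-only dates are pinned to July (mid-year) so binning stays
    deterministic.  Returns None when the field cannot be interpreted.
    """
    raw = raw.strip()
    if not raw:
        return None
    for fmt in ("%Y-%m-%d", "%Y/%m/%d"):
        try:
            return _dt.datetime.strptime(raw, fmt).date()
        except ValueError:
            pass
    m = re.fullmatch(r"(\d{4})[-/](\d{1,2})", raw)
    if m:
        year, month = int(m.group(1)), int(m.group(2))
        if 1 <= month <= 12:
            return _dt.date(year, month, 1)
        return None
    if re.fullmatch(r"\d{4}", raw):
        return _dt.date(int(raw), 7, 1)
    return None


class CorpusReader:
    """Iterable over :class:`DocumentRecord` with a skip counter.

    Iterating yields records in file order; records missing a mandatory
    field (date or abstract) are skipped and tallied in ``n_skipped``.
    """

    def __init__(self, path: str | Path, format: str):
        self.path = Path(path)
        if format not in ("medline-xml", "tabular", "tsv", "jsonl"):
            raise ConfigurationError(f"unknown corpus format: {format!r}")
        self.format = "tabular" if format == "tsv" else format
        self.n_skipped = 0
        if not self.path.exists():
            raise CorpusFormatError(f"corpus file not found: {self.path}")

    def __iter__(self) -> Iterator[DocumentRecord]:
        if self.format == "tabular":
            yield from self._iter_tabular()
        elif self.format == "jsonl":
            yield from self._iter_jsonl()
        else:
            yield from self._iter_medline_xml()

    def _emit(self, doc_id, date_raw, title, abstract) -> DocumentRecord | None:
        date = _parse_date(date_raw) if isinstance(date_raw, str) else date_raw
        abstract = (abstract or "").strip()
        if not doc_id or date is None or not abstract:
            self.n_skipped += 1
            return None
        return DocumentRecord(doc_id=str(doc_id), date=date, title=(title or "").strip(), abstract=abstract)

    def _iter_tabular(self):
        offset = 0
        with open(self.path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh):
                raw = line.rstrip("\n")
                if lineno == 0 and raw.split("\t")[:2] == ["doc_id", "date"]:
                    offset += len(line.encode("utf-8"))
                    continue
                if not raw.strip():
                    offset += len(line.encode("utf-8"))
                    continue
                parts = raw.split("\t")
                if len(parts) != 4:
                    raise CorpusFormatError(
                        f"expected 4 tab-separated columns, got {len(parts)} on line {lineno + 1}",
                        byte_offset=offset,
                    )
                rec = self._emit(*parts)
                if rec is not None:
                    yield rec
                offset += len(line.encode("utf-8"))

    def _iter_jsonl(self):
        offset = 0
        with open(self.path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh):
                if line.strip():
                    try:
                        obj = json.loads(line)
                    except json.JSONDecodeError as exc:
                        raise CorpusFormatError(
                            f"invalid JSON on line {lineno + 1}: {exc}", byte_offset=offset
                        ) from exc
                    rec = self._emit(
                        obj.get("doc_id"), obj.get("date", ""), obj.get("title", ""), obj.get("abstract", "")
                    )
                    if rec is not None:
                        yield rec
                offset += len(line.encode("utf-8"))

    def _iter_medline_xml(self):
        try:
            tree = ET.parse(self.path)
        except ET.ParseError as exc:
            # expat positions are (line, column); report the byte offset of the line start
            raise CorpusFormatError(f"XML parse error: {exc}", byte_offset=getattr(exc, "position", (0, 0))[1]) from exc
        root = tree.getroot()
        articles = root.iter("PubmedArticle")
        for art in articles:
            pmid = art.findtext(".//PMID")
            title = art.findtext(".//ArticleTitle") or ""
            abstract = " ".join(
                (el.text or "").strip() for el in art.findall(".//Abstract/AbstractText")
            ).strip()
            date = self._medline_date(art)
            rec = self._emit(pmid, date, title, abstract)
            if rec is not None:
                yield rec

    @staticmethod
    def _medline_date(art) -> _dt.date | None:
        node = art.find(".//Article/Journal/JournalIssue/PubDate")
        if node is None:
            node = art.find(".//PubDate")
        if node is None:
            return None
        year = node.findtext("Year")
        if not year:
            return None
        month_raw = (node.findtext("Month") or "").strip().lower()
        if month_raw in _MONTH_NAMES:
            month = _MONTH_NAMES[month_raw]
        elif month_raw.isdigit() and 1 <= int(month_raw) <= 12:
            month = int(month_raw)
        else:
            month = 7  # year-only -> mid-year
        return _dt.date(int(year), month, 1)


def read_corpus(path: str | Path, format: str) -> CorpusReader:
    """Open a corpus file and return a re-iterable record stream.

    The returned reader exposes ``n_skipped``, the number of records dropped
    for missing a date or abstract (valid after a full iteration).
    """
    return CorpusReader(path, format)


def _clean_text(text: str) -> str:
    """Lowercase and remove digits/punctuation other than '-' and '+'."""
    text = text.lower()
    text = re.sub(r"[^a-z\-+]+", " ", text)
    return re.sub(r" +", " ", text).strip()


def _normalize_token(tok: str) -> str | None:
    tok = re.sub(r"[-+]{2,}", lambda m: m.group(0)[0], tok).strip("-+")
    if tok and TOKEN_RE.match(tok):
        return tok
    return None


import functools


@functools.lru_cache(maxsize=32)
def _compile_merge_patterns(merge_list: tuple[str, ...]):
    """One regex per phrase over cleaned text, longest phrase first."""
    cleaned = []
    for phrase in merge_list:
        c = _clean_text(phrase)
        if " " in c:  # single-word entries need no merging
            cleaned.append(c)
    cleaned.sort(key=lambda p: (-len(p.split()), -len(p), p))
    return [
        (re.compile(r"(?<![a-z\-+])" + re.escape(p) + r"(?![a-z\-+])"), p.replace(" ", "+"))
        for p in cleaned
    ]


def tokenize_text(text: str, merge_list: Sequence[str] = ()) -> list[str]:
    """Clean, merge multiword phrases into '+'-joined tokens, and tokenize."""
    cleaned = _clean_text(text)
    for pattern, replacement in _compile_merge_patterns(tuple(merge_list)):
        cleaned = pattern.sub(replacement, cleaned)
    tokens = []
    for raw in cleaned.split():
        tok = _normalize_token(raw)
        if tok is not None:
            tokens.append(tok)
    return tokens


def preprocess(
    doc: DocumentRecord,
    merge_list: Sequence[str] = (),
    include_title: bool = False,
) -> TokenizedDocument:
    """Turn a record into a :class:`TokenizedDocument`.

    By default only the abstract is tokenized; pass ``include_title=True``
    to prepend the title tokens.
    """
    text = f"{doc.title} {doc.abstract}" if include_title else doc.abstract
    return TokenizedDocument(doc_id=doc.doc_id, date=doc.date, tokens=tuple(tokenize_text(text, merge_list)))


def filter_span(
    docs: Iterable[DocumentRecord],
    start: _dt.date,
    end: _dt.date,
) -> Iterator[DocumentRecord]:
    """Keep records with start <= date <= end (month granularity), order preserved."""
    if (start.year, start.month) > (end.year, end.month):
        raise ConfigurationError(f"inverted span: {start} > {end}")
    lo, hi = (start.year, start.month), (end.year, end.month)
    for doc in docs:
        if lo <= (doc.date.year, doc.date.month) <= hi:
            yield doc


def load_merge_list(path: str | Path) -> list[str]:
    """Read a merge list: one lowercase phrase per line, blanks ignored."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    return [ln.strip().lower() for ln in lines if ln.strip()]
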