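"""Abstract-corpus ingestion, sentence segmentation and subset selection.

A corpus is a list of :class:`DocumentRecord` (one per article).  Sentences
are addressed by ``(doc_id, sent_index)`` with 0-based character offsets into
the concatenation ``title + "\\n" + abstract``; title sentences precede
abstract sentences.  Subsets of the literature (e.g. the vaccine-related
articles) are selected by token-boundary term matchers.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from lxml import etree

__all__ = [
    "DocumentRecord",
    "Sentence",
    "TermMatcher",
    "DEFAULT_ABBREVIATIONS",
    "VACCINE_VARIANTS",
    "read_corpus",
    "write_corpus",
    "split_sentences",
    "subset_corpus",
]

#: Abbreviations that must not terminate a sentence.
DEFAULT_ABBREVIATIONS = ("E.", "sp.", "et al.", "Fig.", "vs.")

#: Surface variants of the generic term "vaccine" used to define the
#: vaccine-related literature subset.
VACCINE_VARIANTS = (
    "vaccine",
    "vaccines",
    "vaccination",
    "vaccinations",
    "vaccinated",
    "vaccinating",
)


@dataclass(frozen=True)
class DocumentRecord:
    """One article: a stable identifier plus title and abstract text."""

    doc_id: str
    title: str
    abstract: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be nonempty")
        if not self.title and not self.abstract:
            raise ValueError(f"document {self.doc_id!r}: title and abstract both empty")

    @property
    def source(self) -> str:
        """Concatenated text all sentence offsets refer to."""
        return self.title + "\n" + self.abstract


@dataclass(frozen=True)
class Sentence:
    """A sentence with its half-open character span in the document source."""

    doc_id: str
    sent_index: int
    text: str
    char_start: int
    char_end: int


_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def _tokens(text: str) -> list[str]:
    return [m.group(0).lower() for m in _TOKEN_RE.finditer(text)]


class TermMatcher:
    """Token-boundary, case-insensitive matcher over a list of surface terms.

    Multi-word terms match as contiguous token subsequences, so ``"BCG
    vaccine"`` matches "the BCG vaccine trial" but the prefix ``"vaccin"``
    does not match "vaccination".
    """

    def __init__(self, terms: Iterable[str]):
        self.terms = [t for t in (t.strip() for t in terms) if t]
        if not self.terms:
            raise ValueError("term matcher requires at least one term")
        self._term_tokens = [tuple(_tokens(t)) for t in self.terms]

    def matches(self, text: str) -> bool:
        toks = _tokens(text)
        for term in self._term_tokens:
            if not term:
                continue
            w = len(term)
            for i in range(len(toks) - w + 1):
                if tuple(toks[i : i + w]) == term:
                    return True
        return False

    def __or__(self, other: "TermMatcher") -> "TermMatcher":
        return TermMatcher(self.terms + other.terms)


def read_corpus(path: str | Path, format: str = "tsv") -> list[DocumentRecord]:
    """Read an abstract corpus from TSV (doc_id/title/abstract) or MEDLINE XML."""
    path = Path(path)
    if format == "tsv":
        docs = _read_tsv(path)
    elif format == "medline_xml":
        docs = _read_medline_xml(path)
    else:
        raise ValueError(f"unknown corpus format: {format!r}")
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValueError(f"duplicate doc_id {d.doc_id!r} in {path}")
        seen.add(d.doc_id)
    return docs


def _read_tsv(path: Path) -> list[DocumentRecord]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"doc_id", "title", "abstract"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: TSV header must contain doc_id/title/abstract")
        docs = []
        for lineno, row in enumerate(reader, start=2):
            if row["doc_id"] is None:
                raise ValueError(f"{path}:{lineno}: malformed row")
            try:
                docs.append(
                    DocumentRecord(row["doc_id"], row["title"] or "", row["abstract"] or "")
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return docs


def _read_medline_xml(path: Path) -> list[DocumentRecord]:
    tree = etree.parse(str(path))
    docs = []
    for art in tree.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID")
        if not pmid:
            raise ValueError(f"{path}: PubmedArticle without PMID")
        title = art.findtext(".//ArticleTitle") or ""
        abstract = " ".join(
            "".join(node.itertext()).strip()
            for node in art.iter("AbstractText")
        ).strip()
        docs.append(DocumentRecord(pmid, title, abstract))
    return docs


def write_corpus(docs: Sequence[DocumentRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["doc_id", "title", "abstract"])
        for d in docs:
            writer.writerow([d.doc_id, d.title, d.abstract])


_SPLIT_RE = re.compile(r"[.?!](?=\s+[A-Z0-9])")


def _split_segment(text: str, abbreviations: Sequence[str]) -> list[tuple[int, int]]:
    """Half-open spans of sentences inside one text segment (title or abstract)."""
    boundaries = []
    for m in _SPLIT_RE.finditer(text):
        end = m.end()  # position just past the punctuation mark
        prefix = text[:end]
        if any(
            prefix.endswith(abbr)
            and (len(prefix) == len(abbr) or not prefix[-len(abbr) - 1].isalnum())
            for abbr in abbreviations
        ):
            continue
        boundaries.append(end)
    spans = []
    start = 0
    for b in boundaries + [len(text)]:
        raw = text[start:b]
        lead = len(raw) - len(raw.lstrip())
        trail = len(raw) - len(raw.rstrip())
        s, e = start + lead, b - trail
        if s < e:
            spans.append((s, e))
        start = b
    return spans


def split_sentences(
    doc: DocumentRecord,
    abbreviations: Sequence[str] = DEFAULT_ABBREVIATIONS,
) -> list[Sentence]:
    """Segment a document into sentences with offsets into ``doc.source``.

    Rule-based: a sentence ends at ``.?!`` followed by whitespace and an
    uppercase letter or digit, unless the text up to the punctuation ends in
    a known abbreviation.  The title is one sentence unless it contains
    sentence-final punctuation itself.
    """
    source = doc.source
    sentences: list[Sentence] = []
    idx = 0
    segments = [(0, doc.title)]
    segments.append((len(doc.title) + 1, doc.abstract))
    for offset, segment in segments:
        for s, e in _split_segment(segment, abbreviations):
            sentences.append(
                Sentence(doc.doc_id, idx, source[offset + s : offset + e], offset + s, offset + e)
            )
            idx += 1
    return sentences


def subset_corpus(
    docs: Sequence[DocumentRecord], matcher: TermMatcher
) -> list[DocumentRecord]:
    """Documents whose title or abstract contains at least one matcher term."""
    return [d for d in docs if matcher.matches(d.title) or matcher.matches(d.abstract)]
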