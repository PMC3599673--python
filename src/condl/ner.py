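"""Dictionary- and rule-based named-entity tagging of genes and vaccines.

Gene mentions are normalized to official symbols from a HGNC-style lexicon;
vaccine mentions are matched against the leaf terms of a vaccine ontology
(typed ``vaccine_specific``) or against a list of generic surface variants
("vaccine", "vaccination", ...; typed ``vaccine_general``).

Matching rules (normative for this package):

* surfaces are normalized by lowercasing, mapping Greek letters to their
  spelled-out names, and collapsing runs of hyphens/whitespace to a single
  space; every indexed form is additionally indexed with internal separators
  removed, so ``IL-6`` and ``IL6`` are interchangeable;
* candidate surfaces of length <= 2 characters must match an indexed form
  case-sensitively (prevents tagging common short words);
* a surface that maps to more than one official symbol is dropped unless it
  equals one of those official symbols exactly (precision-first);
* matches start and end at alphanumeric token boundaries, and tagging is
  longest-match-wins, left to right.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Sentence, VACCINE_VARIANTS
from .ontology import Ontology, leaf_terms

__all__ = [
    "GeneLexicon",
    "Mention",
    "normalize_surface",
    "load_gene_lexicon",
    "build_vaccine_index",
    "tag_sentence",
    "write_mentions",
    "read_mentions",
]

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta",
    "ε": "epsilon", "κ": "kappa", "λ": "lambda", "σ": "sigma",
    "Α": "alpha", "Β": "beta", "Γ": "gamma", "Δ": "delta",
}

_SEP_RE = re.compile(r"[-\s]+")
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


def normalize_surface(surface: str) -> str:
    """Canonical lookup form: greek spelled out, lowercase, separators → space."""
    for greek, name in _GREEK.items():
        surface = surface.replace(greek, name)
    return _SEP_RE.sub(" ", surface.strip()).lower()


def _index_keys(surface: str) -> set[str]:
    base = normalize_surface(surface)
    return {base, base.replace(" ", "")} - {""}


@dataclass
class GeneLexicon:
    """Gene dictionary: official symbols, full names and synonyms, indexed."""

    entries: list[tuple[str, str, list[str]]]
    index: dict[str, set[str]]
    exact_short: dict[str, set[str]]  # raw surfaces of length <= 2, case kept
    symbols: set[str]

    def resolve(self, surface: str) -> set[str]:
        """Symbols a candidate surface maps to, after case and ambiguity rules."""
        if len(surface) <= 2:
            symbols = set(self.exact_short.get(surface, ()))
        else:
            symbols = set()
            for key in _index_keys(surface):
                symbols |= self.index.get(key, set())
        if len(symbols) > 1:
            return {surface} if surface in symbols else set()
        return symbols


def load_gene_lexicon(path: str | Path) -> GeneLexicon:
    """Load a TSV lexicon with columns symbol / name / synonyms (pipe-separated)."""
    entries: list[tuple[str, str, list[str]]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"symbol", "name", "synonyms"}.issubset(
            reader.fieldnames
        ):
            raise ValueError(f"{path}: lexicon TSV must have symbol/name/synonyms columns")
        for row in reader:
            synonyms = [s for s in (row["synonyms"] or "").split("|") if s]
            entries.append((row["symbol"], row["name"] or "", synonyms))
    if not entries:
        raise ValueError(f"{path}: empty gene lexicon")
    symbols = [sym for sym, _, _ in entries]
    if len(symbols) != len(set(symbols)):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValueError(f"{path}: duplicate official symbols {dupes}")

    index: dict[str, set[str]] = {}
    exact_short: dict[str, set[str]] = {}
    for sym, name, synonyms in entries:
        for form in [sym, name, *synonyms]:
            if not form:
                continue
            for key in _index_keys(form):
                index.setdefault(key, set()).add(sym)
            if len(form) <= 2:
                exact_short.setdefault(form, set()).add(sym)
    return GeneLexicon(entries, index, exact_short, set(symbols))


def build_vaccine_index(onto: Ontology, root_id: str) -> dict[str, str]:
    """Lookup form → term id over the labels/synonyms of leaves under root.

    A form claimed by more than one leaf term is dropped (ambiguous).
    """
    claimed: dict[str, set[str]] = {}
    for tid in sorted(leaf_terms(onto, root_id)):
        rec = onto.terms[tid]
        for form in (rec.label, *rec.synonyms):
            for key in _index_keys(form):
                claimed.setdefault(key, set()).add(tid)
    return {key: next(iter(tids)) for key, tids in claimed.items() if len(tids) == 1}


@dataclass(frozen=True)
class Mention:
    """A typed, normalized entity occurrence inside one sentence."""

    doc_id: str
    sent_index: int
    char_start: int  # sentence-local, 0-based half-open
    char_end: int
    surface: str
    etype: str  # gene | vaccine_specific | vaccine_general
    norm_id: str


_MAX_MENTION_TOKENS = 6
_JOIN_RE = re.compile(r"^[-\s]*$")


def tag_sentence(
    sent: Sentence,
    lex: GeneLexicon | None,
    onto: Ontology | None = None,
    vaccine_root: str | None = None,
    vaccine_variants: Sequence[str] = VACCINE_VARIANTS,
    _vaccine_index: dict[str, str] | None = None,
) -> list[Mention]:
    """Tag gene and vaccine mentions in one sentence.

    Non-overlapping, longest-match-wins, scanned left to right.  When a span
    matches several dictionaries, specific vaccines take priority over genes,
    and genes over the generic vaccine variants.
    """
    if _vaccine_index is None:
        _vaccine_index = (
            build_vaccine_index(onto, vaccine_root) if onto and vaccine_root else {}
        )
    variant_keys = {normalize_surface(v) for v in vaccine_variants}
    text = sent.text
    token_spans = [(m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    mentions: list[Mention] = []
    i = 0
    while i < len(token_spans):
        found = None
        max_j = min(i + _MAX_MENTION_TOKENS, len(token_spans))
        for j in range(max_j, i, -1):  # longest candidate first
            start = token_spans[i][0]
            end = token_spans[j - 1][1]
            # inter-token gaps must be hyphen/whitespace only
            if any(
                not _JOIN_RE.match(text[token_spans[t][1] : token_spans[t + 1][0]])
                for t in range(i, j - 1)
            ):
                continue
            surface = text[start:end]
            key = normalize_surface(surface)
            if key in _vaccine_index:
                found = (j, start, end, surface, "vaccine_specific", _vaccine_index[key])
                break
            if lex is not None:
                symbols = lex.resolve(surface)
                if len(symbols) == 1:
                    found = (j, start, end, surface, "gene", next(iter(symbols)))
                    break
            if key in variant_keys:
                found = (j, start, end, surface, "vaccine_general", "vaccine")
                break
        if found:
            j, start, end, surface, etype, norm = found
            mentions.append(
                Mention(sent.doc_id, sent.sent_index, start, end, surface, etype, norm)
            )
            i = j
        else:
            i += 1
    return mentions


_MENTION_COLUMNS = ["doc_id", "sent_index", "char_start", "char_end", "surface", "etype", "norm_id"]


def write_mentions(mentions: Iterable[Mention], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MENTION_COLUMNS)
        for m in mentions:
            writer.writerow(
                [m.doc_id, m.sent_index, m.char_start, m.char_end, m.surface, m.etype, m.norm_id]
            )


def read_mentions(path: str | Path) -> list[Mention]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        return [
            Mention(
                row["doc_id"],
                int(row["sent_index"]),
                int(row["char_start"]),
                int(row["char_end"]),
                row["surface"],
                row["etype"],
                row["norm_id"],
            )
            for row in reader
        ]
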