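"""Candidate interaction sentences and shortest dependency paths.

A sentence is a *candidate* when it contains an interaction keyword plus two
distinct tagged genes, or a gene and a vaccine.  For each candidate pair the
shortest path between the two entity head tokens in the sentence's dependency
tree is extracted and serialized as an alternating node/edge token sequence:
node tokens are lowercased lemmas with the endpoints replaced by ``ENTITYA``
/ ``ENTITYB`` (and any other tagged entity on the path by ``ENTITYX``); edge
tokens are dependency relations suffixed with a traversal-direction marker
(``<`` = step toward the head, ``>`` = step toward the dependent).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus import Sentence
from .ner import Mention

__all__ = [
    "DepParse",
    "Token",
    "CandidatePair",
    "DependencyPath",
    "DegeneratePairError",
    "load_keywords",
    "default_keywords",
    "find_candidates",
    "read_conllu",
    "write_conllu",
    "shortest_dep_path",
]


@dataclass(frozen=True)
class Token:
    tid: int  # 1-based
    form: str
    lemma: str
    head: int  # 0 = root
    deprel: str


@dataclass(frozen=True)
class DepParse:
    doc_id: str
    sent_index: int
    tokens: tuple[Token, ...]

    def __post_init__(self) -> None:
        where = f"parse {self.doc_id}#{self.sent_index}"
        tids = [t.tid for t in self.tokens]
        if tids != list(range(1, len(tids) + 1)):
            raise ValueError(f"{where}: token ids not consecutive from 1")
        roots = [t for t in self.tokens if t.head == 0]
        if len(roots) != 1:
            raise ValueError(f"{where}: expected exactly one root, found {len(roots)}")
        for t in self.tokens:
            if t.head and not 1 <= t.head <= len(self.tokens):
                raise ValueError(f"{where}: token {t.tid} head {t.head} does not exist")


@dataclass(frozen=True)
class CandidatePair:
    doc_id: str
    sent_index: int
    mention_a: Mention
    mention_b: Mention
    keyword: str
    pair_kind: str  # gene_gene | gene_vaccine


@dataclass(frozen=True)
class DependencyPath:
    node_tokens: tuple[str, ...]
    edge_tokens: tuple[str, ...]

    @property
    def sequence(self) -> tuple[str, ...]:
        seq = [self.node_tokens[0]]
        for edge, node in zip(self.edge_tokens, self.node_tokens[1:]):
            seq.extend([edge, node])
        return tuple(seq)


class DegeneratePairError(ValueError):
    """Both mentions align to the same token; no path exists between them."""


_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")
_SUFFIXES = ("ing", "ed", "es", "d", "s")


def _stems(word: str) -> set[str]:
    """The word plus light-stemmed variants, stripping -s/-es/-d/-ed/-ing
    when the remaining stem has >= 4 characters ("induced" yields both
    "induc" and "induce", so e-final verb lemmas still match)."""
    word = word.lower()
    out = {word}
    for suf in _SUFFIXES:
        if word.endswith(suf) and len(word) - len(suf) >= 4:
            out.add(word[: -len(suf)])
    return out


def load_keywords(path: str | Path) -> set[str]:
    """One keyword per line, '#' comments; entries are stemmed on load."""
    keywords: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                keywords |= _stems(line)
    if not keywords:
        raise ValueError(f"{path}: empty keyword list")
    return keywords


def default_keywords() -> set[str]:
    """The packaged interaction-keyword stem list."""
    text = resources.files("condl.data").joinpath("keywords.txt").read_text()
    keywords: set[str] = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            keywords |= _stems(line)
    return keywords


def _match_keyword(text: str, keywords: set[str]) -> str | None:
    for m in _TOKEN_RE.finditer(text):
        if _stems(m.group(0)) & keywords:
            return m.group(0)
    return None


def find_candidates(
    sent: Sentence, mentions: Sequence[Mention], keywords: set[str]
) -> list[CandidatePair]:
    """Entity pairs in a keyword-bearing sentence.

    One pair per unordered combination of mentions with distinct normalized
    ids: gene-gene pairs need two different gene symbols; gene-vaccine pairs
    one gene plus one vaccine mention.  Vaccine-vaccine pairs are not
    extracted.
    """
    if not keywords:
        raise ValueError("keyword set is empty")
    keyword = _match_keyword(sent.text, keywords)
    if keyword is None:
        return []
    pairs: list[CandidatePair] = []
    seen: set[frozenset[str]] = set()
    ms = sorted(mentions, key=lambda m: m.char_start)
    for i in range(len(ms)):
        for j in range(i + 1, len(ms)):
            a, b = ms[i], ms[j]
            if a.norm_id == b.norm_id:
                continue
            kinds = {a.etype, b.etype}
            if kinds == {"gene"}:
                kind = "gene_gene"
            elif "gene" in kinds and kinds & {"vaccine_specific", "vaccine_general"}:
                kind = "gene_vaccine"
            else:
                continue
            key = frozenset((a.norm_id, b.norm_id))
            if key in seen:
                continue
            seen.add(key)
            pairs.append(CandidatePair(sent.doc_id, sent.sent_index, a, b, keyword, kind))
    return pairs


def read_conllu(path: str | Path) -> list[DepParse]:
    """Read CoNLL-U sentence blocks carrying doc_id/sent_index metadata.

    Multiword-token (``1-2``) and empty-node (``1.1``) lines are skipped.
    """
    parses: list[DepParse] = []
    meta: dict[str, str] = {}
    tokens: list[Token] = []

    def flush(lineno: int) -> None:
        nonlocal meta, tokens
        if not tokens:
            meta = {}
            return
        if "doc_id" not in meta or "sent_index" not in meta:
            raise ValueError(f"{path}:{lineno}: block missing doc_id/sent_index metadata")
        parses.append(DepParse(meta["doc_id"], int(meta["sent_index"]), tuple(tokens)))
        meta, tokens = {}, []

    with open(path, encoding="utf-8") as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                flush(lineno)
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    meta[key.strip()] = value.strip()
                continue
            cols = line.split("\t")
            if len(cols) != 10:
                raise ValueError(f"{path}:{lineno}: expected 10 columns, got {len(cols)}")
            tid = cols[0]
            if "-" in tid or "." in tid:
                continue
            tokens.append(Token(int(tid), cols[1], cols[2], int(cols[6]), cols[7]))
        flush(lineno + 1)
    return parses


def write_conllu(parses: Iterable[DepParse], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for p in parses:
            fh.write(f"# doc_id = {p.doc_id}\n# sent_index = {p.sent_index}\n")
            for t in p.tokens:
                fh.write(
                    f"{t.tid}\t{t.form}\t{t.lemma}\t_\t_\t_\t{t.head}\t{t.deprel}\t_\t_\n"
                )
            fh.write("\n")


def _token_char_spans(parse: DepParse, text: str) -> list[tuple[int, int]]:
    """Locate token forms in the sentence text by a left-to-right scan."""
    spans = []
    cursor = 0
    for t in parse.tokens:
        pos = text.find(t.form, cursor)
        if pos < 0:
            raise ValueError(
                f"parse {parse.doc_id}#{parse.sent_index}: token {t.form!r} "
                f"not found in sentence text"
            )
        spans.append((pos, pos + len(t.form)))
        cursor = pos + len(t.form)
    return spans


def _align_mention(
    parse: DepParse, spans: Sequence[tuple[int, int]], mention: Mention
) -> int:
    """Head token index (0-based) for a mention: the overlapped token whose
    head lies outside the mention, else the rightmost overlapped token."""
    overlapped = [
        i
        for i, (s, e) in enumerate(spans)
        if s < mention.char_end and mention.char_start < e
    ]
    if not overlapped:
        raise ValueError(
            f"mention {mention.surface!r} does not align to any token of "
            f"parse {parse.doc_id}#{parse.sent_index}"
        )
    inside = set(overlapped)
    heads_outside = [
        i for i in overlapped if (parse.tokens[i].head - 1) not in inside
    ]
    return heads_outside[-1] if heads_outside else overlapped[-1]


def _node_token(token: Token) -> str:
    lemma = token.lemma if token.lemma and token.lemma != "_" else token.form
    return lemma.lower()


def shortest_dep_path(
    parse: DepParse,
    a: Mention,
    b: Mention,
    sentence_text: str,
    other_mentions: Sequence[Mention] = (),
) -> DependencyPath:
    """Shortest (unique) path between two entity head tokens in the dep tree."""
    spans = _token_char_spans(parse, sentence_text)
    ia = _align_mention(parse, spans, a)
    ib = _align_mention(parse, spans, b)
    if ia == ib:
        raise DegeneratePairError(
            f"degenerate pair: {a.surface!r} and {b.surface!r} align to the "
            f"same token in parse {parse.doc_id}#{parse.sent_index}"
        )
    # undirected adjacency over dependency arcs
    n = len(parse.tokens)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i, t in enumerate(parse.tokens):
        if t.head:
            adj[i].append(t.head - 1)
            adj[t.head - 1].append(i)
    # BFS from ia to ib
    prev: dict[int, int] = {ia: -1}
    queue = [ia]
    while queue:
        nxt = []
        for u in queue:
            for v in adj[u]:
                if v not in prev:
                    prev[v] = u
                    nxt.append(v)
        if ib in prev:
            break
        queue = nxt
    if ib not in prev:
        raise ValueError(
            f"no path between tokens in parse {parse.doc_id}#{parse.sent_index}"
        )
    path = [ib]
    while path[-1] != ia:
        path.append(prev[path[-1]])
    path.reverse()

    entity_tokens: dict[int, str] = {}
    for m in other_mentions:
        for i, (s, e) in enumerate(spans):
            if s < m.char_end and m.char_start < e:
                entity_tokens[i] = "ENTITYX"
    node_tokens = []
    for i in path:
        if i == ia:
            node_tokens.append("ENTITYA")
        elif i == ib:
            node_tokens.append("ENTITYB")
        elif i in entity_tokens:
            node_tokens.append(entity_tokens[i])
        else:
            node_tokens.append(_node_token(parse.tokens[i]))
    edge_tokens = []
    for u, v in zip(path, path[1:]):
        if parse.tokens[u].head - 1 == v:  # step toward the head
            edge_tokens.append(parse.tokens[u].deprel + "<")
        else:  # v's head is u: step toward the dependent
            edge_tokens.append(parse.tokens[v].deprel + ">")
    return DependencyPath(tuple(node_tokens), tuple(edge_tokens))


def write_paths(
    rows: Iterable[tuple[CandidatePair, DependencyPath]], path: str | Path
) -> None:
    """TSV of candidate pairs with their space-joined path sequences."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["doc_id", "sent_index", "norm_a", "norm_b", "pair_kind", "keyword", "path"]
        )
        for cand, dep in rows:
            writer.writerow(
                [
                    cand.doc_id,
                    cand.sent_index,
                    cand.mention_a.norm_id,
                    cand.mention_b.norm_id,
                    cand.pair_kind,
                    cand.keyword,
                    " ".join(dep.sequence),
                ]
            )
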