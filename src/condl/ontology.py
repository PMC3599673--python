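"""OBO ontology loading and transitive is_a closure.

Only the subclass (is_a) hierarchy is used: the tagging dictionary for
specific vaccines is the set of leaf terms under the root "vaccine" term,
and ancestor sets are transitive closures over is_a.  No OWL reasoning.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import obonet

__all__ = ["TermRecord", "Ontology", "load_obo", "ancestors", "descendants", "leaf_terms"]


@dataclass(frozen=True)
class TermRecord:
    label: str
    synonyms: tuple[str, ...]
    parents: frozenset[str]


@dataclass
class Ontology:
    """Acyclic is_a hierarchy of named terms."""

    terms: dict[str, TermRecord]
    children: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        self.children = {tid: set() for tid in self.terms}
        for tid, rec in self.terms.items():
            for p in rec.parents:
                if p not in self.terms:
                    raise ValueError(f"term {tid}: dangling is_a parent {p!r}")
                self.children[p].add(tid)
        g = nx.DiGraph(
            (tid, p) for tid, rec in self.terms.items() for p in rec.parents
        )
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"is_a cycle detected: {cycle}")

    def roots(self) -> set[str]:
        return {tid for tid, rec in self.terms.items() if not rec.parents}


_SYNONYM_RE = re.compile(r'^"(.*)"')


def load_obo(path: str | Path) -> Ontology:
    """Parse an OBO 1.2 flat file; obsolete terms are skipped."""
    graph = obonet.read_obo(str(path), ignore_obsolete=True)
    terms: dict[str, TermRecord] = {}
    dangling: list[str] = []
    for tid, data in graph.nodes(data=True):
        if "name" not in data:
            dangling.append(tid)
            continue
        synonyms = []
        for raw in data.get("synonym", []):
            m = _SYNONYM_RE.match(raw)
            synonyms.append(m.group(1) if m else raw)
        terms[tid] = TermRecord(
            label=data["name"],
            synonyms=tuple(synonyms),
            parents=frozenset(data.get("is_a", [])),
        )
    for tid in dangling:
        referrers = [c for c, rec in terms.items() if tid in rec.parents]
        raise ValueError(f"dangling is_a parent {tid!r} referenced by {referrers}")
    return Ontology(terms)


def ancestors(onto: Ontology, term_id: str) -> set[str]:
    """Reflexive-free transitive closure of is_a above ``term_id``."""
    if term_id not in onto.terms:
        raise KeyError(f"unknown term id {term_id!r}")
    seen: set[str] = set()
    stack = list(onto.terms[term_id].parents)
    while stack:
        t = stack.pop()
        if t not in seen:
            seen.add(t)
            stack.extend(onto.terms[t].parents)
    return seen


def descendants(onto: Ontology, term_id: str) -> set[str]:
    """Reflexive-free transitive closure of is_a below ``term_id``."""
    if term_id not in onto.terms:
        raise KeyError(f"unknown term id {term_id!r}")
    seen: set[str] = set()
    stack = list(onto.children[term_id])
    while stack:
        t = stack.pop()
        if t not in seen:
            seen.add(t)
            stack.extend(onto.children[t])
    return seen


def leaf_terms(onto: Ontology, root_id: str) -> set[str]:
    """Strict descendants of ``root_id`` that have no children of their own.

    The root itself is excluded even when it is childless: the leaf set is
    the dictionary of *specific* terms below the general root term.
    """
    return {t for t in descendants(onto, root_id) if not onto.children[t]}
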