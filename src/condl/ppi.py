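"""Comparison of the literature-derived network with an external PPI network.

The PPI edge list (HPRD-style TSV of interactor symbol pairs) is normalized
through the gene lexicon and, by default, restricted to pairs among the
literature network's genes before comparison — the overlap question is "how
many of the literature interactions are known physical interactions among
these same genes", not "how much of the PPI database did we recover".  The
merged network tags each gene-gene edge ``literature``, ``ppi`` or ``both``
and supports indirect-interaction hypotheses: if a-b is a shared anchor
edge, a literature-only partner x of a and a PPI-only partner y of b may
interact indirectly through the anchor.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Collection

import networkx as nx

from .ner import GeneLexicon
from .network import gene_gene_edges

__all__ = [
    "OverlapCounts",
    "IndirectHypothesis",
    "read_ppi",
    "overlap",
    "indirect_hypotheses",
]


@dataclass(frozen=True)
class OverlapCounts:
    lit_only: int
    ppi_only: int
    both: int


@dataclass(frozen=True)
class IndirectHypothesis:
    anchor: tuple[str, str]
    candidate: tuple[str, str]  # (x, y): x literature-side, y ppi-side
    path: tuple[str, str, str, str]  # x - anchor_a - anchor_b - y
    rationale: str


def read_ppi(
    path: str | Path, lex: GeneLexicon | None = None
) -> tuple[set[frozenset[str]], int]:
    """Read a PPI edge list; returns (undirected edges, n rows skipped).

    Symbols are normalized through the lexicon when one is given; rows with
    an unmappable symbol are skipped and counted.  Self-interactions are
    dropped and reciprocal duplicates collapse.
    """
    edges: set[frozenset[str]] = set()
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: PPI row needs >= 2 columns")
            pair = []
            for raw in fields[:2]:
                if lex is None:
                    pair.append(raw)
                    continue
                symbols = lex.resolve(raw)
                if len(symbols) != 1:
                    pair = None
                    break
                pair.append(next(iter(symbols)))
            if pair is None:
                skipped += 1
                continue
            a, b = pair
            if a == b:
                continue
            edges.add(frozenset((a, b)))
    return edges, skipped


def overlap(
    lit_net: nx.Graph,
    ppi_edges: Collection[frozenset[str]],
    restrict_to_lit_genes: bool = True,
) -> tuple[OverlapCounts, nx.Graph]:
    """Compare literature gene-gene edges with PPI edges; tag a merged network.

    With ``restrict_to_lit_genes`` (the default) PPI edges touching genes
    outside the literature network are excluded before counting.
    """
    lit_edges = gene_gene_edges(lit_net)
    lit_genes = {n for n in lit_net.nodes if lit_net.nodes[n].get("ntype") == "gene"}
    ppi = set(ppi_edges)
    if restrict_to_lit_genes:
        ppi = {e for e in ppi if e <= lit_genes}
    both = lit_edges & ppi
    counts = OverlapCounts(
        lit_only=len(lit_edges - ppi), ppi_only=len(ppi - lit_edges), both=len(both)
    )
    merged = lit_net.copy()
    for e in both:
        u, v = sorted(e)
        merged.edges[u, v]["source_tag"] = "both"
    for e in ppi - lit_edges:
        u, v = sorted(e)
        for n in (u, v):
            if n not in merged:
                merged.add_node(n, ntype="gene")
        merged.add_edge(
            u, v, evidence=frozenset(), n_sentences=0, max_score=0.0, source_tag="ppi"
        )
    return counts, merged


def _exclusive_neighbors(merged: nx.Graph, node: str, tag: str) -> set[str]:
    return {
        nbr
        for nbr in merged.neighbors(node)
        if merged.edges[node, nbr].get("source_tag") == tag
        and merged.nodes[nbr].get("ntype", "gene") == "gene"
    }


def indirect_hypotheses(
    merged: nx.Graph, anchor: tuple[str, str]
) -> list[IndirectHypothesis]:
    """Fig-4C-style hypotheses around a shared anchor edge.

    For anchor (a, b): every pair of a literature-only gene partner x of a
    and a PPI-only gene partner y of b (and symmetrically with the roles of
    a and b swapped) yields the candidate indirect interaction x ~ y via the
    path x - a - b - y.
    """
    a, b = anchor
    if not merged.has_edge(a, b):
        raise ValueError(f"anchor edge {a}-{b} not present in the merged network")
    out: list[IndirectHypothesis] = []
    seen: set[tuple[str, str, frozenset[str]]] = set()
    for left, right in ((a, b), (b, a)):
        xs = _exclusive_neighbors(merged, left, "literature")
        ys = _exclusive_neighbors(merged, right, "ppi")
        for x in sorted(xs):
            for y in sorted(ys):
                if len({x, y, a, b}) < 4:
                    continue
                key = (left, right, frozenset((x, y)))
                if key in seen:
                    continue
                seen.add(key)
                out.append(
                    IndirectHypothesis(
                        anchor=(left, right),
                        candidate=(x, y),
                        path=(x, left, right, y),
                        rationale=(
                            f"{x} interacts with {left} in the literature network; "
                            f"{y} interacts with {right} in the PPI network; the "
                            f"shared {left}-{right} interaction links them"
                        ),
                    )
                )
    return out


def write_hypotheses(hypotheses: list[IndirectHypothesis], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["x", "anchor_a", "anchor_b", "y", "rationale"])
        for h in hypotheses:
            writer.writerow([*h.path, h.rationale])
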