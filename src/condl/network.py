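"""Interaction-network assembly and Cytoscape-compatible export.

Networks are simple undirected :class:`networkx.Graph` objects.  Nodes carry
``ntype`` ("gene" or "vaccine"); edges carry the evidence sentences that
support them (``evidence``: frozenset of ``(doc_id, sent_index)``),
``n_sentences = |evidence|``, the maximum SVM score seen for the pair, and a
``source_tag`` ("literature" here; "ppi"/"both" after merging with a PPI
network).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Collection, Iterable, Sequence

import networkx as nx

from .classifier import ScoredInteraction

__all__ = [
    "build_network",
    "subnetwork_by_corpus",
    "export_network",
    "read_graphml",
    "network_equal",
    "gene_gene_edges",
]

_VACCINE_TYPES = {"vaccine_specific", "vaccine_general"}


def _node_info(mention) -> tuple[str, str]:
    if mention.etype in _VACCINE_TYPES:
        return mention.norm_id, "vaccine"
    return mention.norm_id, "gene"


def build_network(
    scored: Iterable[ScoredInteraction], threshold: float = 0.0
) -> nx.Graph:
    """Network of positively scored pairs; repeated pairs merge their evidence.

    An occurrence contributes when its SVM decision value exceeds
    ``threshold`` (default 0: "positive confidence scores").
    """
    g = nx.Graph()
    for rec in scored:
        if not rec.score > threshold:
            continue
        a_id, a_type = _node_info(rec.pair.mention_a)
        b_id, b_type = _node_info(rec.pair.mention_b)
        if a_id == b_id:
            continue
        if a_type == "vaccine" and b_type == "vaccine":
            continue
        g.add_node(a_id, ntype=a_type)
        g.add_node(b_id, ntype=b_type)
        ev = (rec.pair.doc_id, rec.pair.sent_index)
        if g.has_edge(a_id, b_id):
            data = g.edges[a_id, b_id]
            data["evidence"] = data["evidence"] | {ev}
            data["n_sentences"] = len(data["evidence"])
            data["max_score"] = max(data["max_score"], rec.score)
        else:
            g.add_edge(
                a_id,
                b_id,
                evidence=frozenset({ev}),
                n_sentences=1,
                max_score=rec.score,
                source_tag="literature",
            )
    return g


def subnetwork_by_corpus(
    scored: Iterable[ScoredInteraction],
    doc_subset: Collection[str],
    threshold: float = 0.0,
) -> nx.Graph:
    """Network built only from evidence in the given document subset."""
    subset = set(doc_subset)
    return build_network(
        (rec for rec in scored if rec.pair.doc_id in subset), threshold
    )


def gene_gene_edges(g: nx.Graph) -> set[frozenset[str]]:
    """Unordered gene pairs connected in the network (vaccine edges excluded)."""
    return {
        frozenset((u, v))
        for u, v in g.edges
        if g.nodes[u]["ntype"] == "gene" and g.nodes[v]["ntype"] == "gene"
    }


def _evidence_str(evidence: frozenset[tuple[str, int]]) -> str:
    return "|".join(f"{d}:{i}" for d, i in sorted(evidence))


def _parse_evidence(text: str) -> frozenset[tuple[str, int]]:
    if not text:
        return frozenset()
    out = set()
    for part in text.split("|"):
        doc, _, idx = part.rpartition(":")
        out.add((doc, int(idx)))
    return frozenset(out)


def export_network(g: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the network as SIF, GraphML or an attribute TSV edge list."""
    path = Path(path)
    if format == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for u, v in sorted(map(sorted, g.edges)):
                fh.write(f"{u}\tinteracts\t{v}\n")
            for n in sorted(g.nodes):
                if g.degree(n) == 0:
                    fh.write(f"{n}\n")
    elif format == "graphml":
        out = nx.Graph()
        for n, data in g.nodes(data=True):
            out.add_node(n, **data)
        for u, v, data in g.edges(data=True):
            attrs = dict(data)
            attrs["evidence"] = _evidence_str(attrs.get("evidence", frozenset()))
            attrs["max_score"] = float(attrs.get("max_score", 0.0))
            out.add_edge(u, v, **attrs)
        nx.write_graphml(out, path)
    elif format == "tsv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(
                ["node_a", "node_b", "n_sentences", "max_score", "source_tag", "evidence"]
            )
            for u, v in sorted(map(sorted, g.edges)):
                data = g.edges[u, v]
                writer.writerow(
                    [
                        u,
                        v,
                        data.get("n_sentences", 0),
                        repr(data.get("max_score", 0.0)),
                        data.get("source_tag", ""),
                        _evidence_str(data.get("evidence", frozenset())),
                    ]
                )
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_graphml(path: str | Path) -> nx.Graph:
    """Read a network written by :func:`export_network`; exact round-trip."""
    raw = nx.read_graphml(path)
    g = nx.Graph()
    for n, data in raw.nodes(data=True):
        g.add_node(str(n), ntype=data.get("ntype", "gene"))
    for u, v, data in raw.edges(data=True):
        g.add_edge(
            str(u),
            str(v),
            evidence=_parse_evidence(data.get("evidence", "")),
            n_sentences=int(data.get("n_sentences", 0)),
            max_score=float(data.get("max_score", 0.0)),
            source_tag=data.get("source_tag", "literature"),
        )
    return g


def network_equal(a: nx.Graph, b: nx.Graph) -> bool:
    """Node/edge identity including types, evidence, counts and tags."""
    if set(a.nodes) != set(b.nodes) or set(map(frozenset, a.edges)) != set(
        map(frozenset, b.edges)
    ):
        return False
    for n in a.nodes:
        if a.nodes[n].get("ntype") != b.nodes[n].get("ntype"):
            return False
    for u, v in a.edges:
        da, db = a.edges[u, v], b.edges[u, v]
        if (
            da.get("evidence") != db.get("evidence")
            or da.get("n_sentences") != db.get("n_sentences")
            or da.get("source_tag") != db.get("source_tag")
            or abs(da.get("max_score", 0.0) - db.get("max_score", 0.0)) > 1e-12
        ):
            return False
    return True
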