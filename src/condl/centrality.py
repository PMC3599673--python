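"""Node centrality, deterministic ranking, and two-network top-k comparison.

Four centrality measures are computed for every node: raw degree,
eigenvector centrality (power iteration on the adjacency matrix), closeness
with the Wasserman-Faust correction for disconnected graphs, and
unnormalized shortest-path betweenness.  Genes are ranked per measure with
competition ranking (ties share a rank; ordering ties broken by node id),
and two networks are compared by the sets of genes ranked in the top k by
at least one measure.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "METRICS",
    "CentralityReport",
    "TopComparison",
    "degree_centrality",
    "eigenvector_centrality",
    "closeness_centrality",
    "betweenness_centrality",
    "compute_report",
    "top_k",
    "compare_top_sets",
    "write_report",
    "write_comparison",
]

METRICS = ("degree", "eigenvector", "closeness", "betweenness")


def degree_centrality(g: nx.Graph) -> dict[str, float]:
    """Raw degree counts."""
    return {n: float(d) for n, d in g.degree()}


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-10, max_iter: int = 10000
) -> dict[str, float]:
    """Dominant adjacency eigenvector by power iteration.

    Uniform positive start, L2 normalization each step; converged when the
    L2 gap between successive iterates falls below ``tol``.  The iteration
    runs on A + I (an identity shift): the dominant eigenvector is unchanged
    but the iteration also converges on bipartite graphs, where the raw
    adjacency spectrum is symmetric and pure power iteration oscillates.
    """
    if g.number_of_edges() == 0:
        raise ValueError("eigenvector centrality undefined on an edgeless graph")
    nodes = sorted(g.nodes)
    adj = nx.to_numpy_array(g, nodelist=nodes)
    x = np.full(len(nodes), 1.0 / np.sqrt(len(nodes)))
    gap = np.inf
    for _ in range(max_iter):
        y = adj @ x + x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValueError("power iteration collapsed to the zero vector")
        y /= norm
        gap = float(np.linalg.norm(y - x))
        x = y
        if gap < tol:
            return dict(zip(nodes, (float(v) for v in x)))
    raise ValueError(
        f"eigenvector centrality did not converge in {max_iter} iterations "
        f"(last iterate gap {gap:.3e})"
    )


def closeness_centrality(g: nx.Graph) -> dict[str, float]:
    """Closeness with the Wasserman-Faust component-size correction.

    Within a component of size n_c, a node's score is
    ((n_c - 1) / total distance) * ((n_c - 1) / (N - 1)); isolated nodes
    score 0.
    """
    return {n: float(v) for n, v in nx.closeness_centrality(g, wf_improved=True).items()}


def betweenness_centrality(g: nx.Graph) -> dict[str, float]:
    """Unnormalized shortest-path betweenness, endpoints excluded,
    each unordered pair counted once."""
    return {
        n: float(v)
        for n, v in nx.betweenness_centrality(g, normalized=False).items()
    }


def _competition_ranks(scores: dict[str, float]) -> tuple[list[str], dict[str, int]]:
    """Deterministic ordering (score desc, id asc) and competition ranks."""
    order = sorted(scores, key=lambda n: (-scores[n], n))
    ranks = {}
    for i, n in enumerate(order):
        if i > 0 and scores[n] == scores[order[i - 1]]:
            ranks[n] = ranks[order[i - 1]]
        else:
            ranks[n] = i + 1
    return order, ranks


@dataclass
class CentralityReport:
    """Scores, deterministic orderings and competition ranks per measure."""

    scores: dict[str, dict[str, float]]  # metric -> node -> score
    orders: dict[str, list[str]]  # metric -> nodes ordered
    ranks: dict[str, dict[str, int]]  # metric -> node -> competition rank

    @property
    def nodes(self) -> list[str]:
        return sorted(next(iter(self.scores.values()), {}))


def compute_report(g: nx.Graph, include_vaccines: bool = False) -> CentralityReport:
    """All four centrality measures on the network.

    Vaccine nodes are excluded from the ranking by default (gene
    prioritization); centralities are still computed on the full graph so
    vaccine connectivity contributes to gene scores.
    """
    metric_fns = {
        "degree": degree_centrality,
        "eigenvector": eigenvector_centrality,
        "closeness": closeness_centrality,
        "betweenness": betweenness_centrality,
    }
    keep = set(g.nodes)
    if not include_vaccines:
        keep = {n for n in keep if g.nodes[n].get("ntype", "gene") != "vaccine"}
    scores, orders, ranks = {}, {}, {}
    for metric, fn in metric_fns.items():
        s = {n: v for n, v in fn(g).items() if n in keep}
        scores[metric] = s
        orders[metric], ranks[metric] = _competition_ranks(s)
    return CentralityReport(scores, orders, ranks)


def top_k(report: CentralityReport, metric: str, k: int) -> list[str]:
    """First k nodes of the deterministic ordering for one measure."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if metric not in report.orders:
        raise KeyError(f"unknown metric {metric!r}")
    return report.orders[metric][:k]


def top_any(report: CentralityReport, k: int) -> set[str]:
    """Nodes in the top k by at least one centrality measure."""
    out: set[str] = set()
    for metric in METRICS:
        out |= set(top_k(report, metric, k))
    return out


@dataclass(frozen=True)
class TopComparison:
    k: int
    both: frozenset[str]
    a_only: frozenset[str]
    b_only: frozenset[str]


def compare_top_sets(
    report_a: CentralityReport, report_b: CentralityReport, k: int = 10
) -> TopComparison:
    """Partition the most-central genes of two networks.

    Membership = ranked in the top k by at least one measure in the
    respective network; genes central in both networks, only in A, or only
    in B form the three groups.
    """
    a = top_any(report_a, k)
    b = top_any(report_b, k)
    return TopComparison(k, frozenset(a & b), frozenset(a - b), frozenset(b - a))


def write_report(report: CentralityReport, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["node"]
            + [f"{m}_score" for m in METRICS]
            + [f"{m}_rank" for m in METRICS]
        )
        for n in report.nodes:
            writer.writerow(
                [n]
                + [repr(report.scores[m][n]) for m in METRICS]
                + [report.ranks[m][n] for m in METRICS]
            )


def write_comparison(
    report_a: CentralityReport,
    report_b: CentralityReport,
    k: int,
    path: str | Path,
    label_a: str = "network_a",
    label_b: str = "network_b",
) -> TopComparison:
    """Write the two-network rank table: per gene, its rank in each measure
    and network, '---' where the gene is outside the top k."""
    comparison = compare_top_sets(report_a, report_b, k)
    genes = sorted(
        comparison.both | comparison.a_only | comparison.b_only,
        key=lambda n: (
            min(
                [report_a.ranks[m].get(n, k + 1) for m in METRICS]
                + [report_b.ranks[m].get(n, k + 1) for m in METRICS]
            ),
            n,
        ),
    )

    def cell(report: CentralityReport, metric: str, gene: str) -> str:
        rank = report.ranks[metric].get(gene)
        return str(rank) if rank is not None and rank <= k else "---"

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["gene"]
            + [f"{label_a}_{m}" for m in METRICS]
            + [f"{label_b}_{m}" for m in METRICS]
            + ["group"]
        )
        for gene in genes:
            if gene in comparison.both:
                group = "both"
            elif gene in comparison.a_only:
                group = label_a
            else:
                group = label_b
            writer.writerow(
                [gene]
                + [cell(report_a, m, gene) for m in METRICS]
                + [cell(report_b, m, gene) for m in METRICS]
                + [group]
            )
    return comparison
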