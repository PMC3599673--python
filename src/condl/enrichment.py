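"""Over-representation analysis of network gene sets.

Given a query gene set (the genes of an interaction network) and a GMT
annotation database, each term is tested for over-representation with the
upper-tail hypergeometric probability P(X >= k) (Fisher's one-sided exact
test) or its conservative EASE variant, which replaces the observed overlap
k by k - 1.  Raw p-values are Benjamini-Hochberg adjusted across all tested
terms; terms with overlap k < 2 are not tested.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Collection, Sequence

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationDB",
    "EnrichmentResult",
    "load_gmt",
    "hypergeom_upper_tail",
    "enrich",
    "bh_adjust",
    "write_enrichment",
]


@dataclass
class AnnotationDB:
    """Term -> annotated gene set, over an explicit background universe."""

    terms: dict[str, tuple[str, frozenset[str]]]  # term id -> (name, genes)
    background: frozenset[str]

    def __post_init__(self) -> None:
        for term, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has an empty gene set")
            stray = genes - self.background
            if stray:
                raise ValueError(
                    f"term {term!r} annotates genes missing from the background: "
                    f"{sorted(stray)[:5]}"
                )


def load_gmt(
    path: str | Path, background: Collection[str] | None = None
) -> AnnotationDB:
    """Load a GMT file (term, description, genes...).

    The background defaults to the union of all annotated genes unless an
    explicit universe is supplied.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT row needs term, description and >= 1 gene"
                )
            term, desc = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            terms[term] = (desc, genes)
    union = frozenset().union(*(genes for _, genes in terms.values())) if terms else frozenset()
    bg = frozenset(background) if background is not None else union
    return AnnotationDB(terms, bg)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    for p in pvalues:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {p}")
    if not pvalues:
        return []
    return [float(p) for p in multipletests(list(pvalues), method="fdr_bh")[1]]


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    term_name: str
    k: int  # query ∩ term
    K: int  # term size in background
    n: int  # query size in background
    N: int  # background size
    p_raw: float
    p_adj: float
    significant: bool


def enrich(
    query: Collection[str],
    db: AnnotationDB,
    method: str = "ease",
    alpha: float = 0.05,
    min_overlap: int = 2,
) -> list[EnrichmentResult]:
    """Test every term for over-representation of the query gene set.

    Genes outside the background are ignored; terms overlapping the query by
    fewer than ``min_overlap`` genes are skipped.  Results are sorted by
    adjusted p-value (ties by term id).
    """
    if method not in ("fisher", "ease"):
        raise ValueError(f"unknown method {method!r}")
    effective = frozenset(query) & db.background
    if not effective:
        raise ValueError("query has no genes in the annotation background")
    N, n = len(db.background), len(effective)
    tested = []
    for term in sorted(db.terms):
        name, genes = db.terms[term]
        k = len(effective & genes)
        if k < min_overlap:
            continue
        k_eff = max(k - 1, 0) if method == "ease" else k
        p = hypergeom_upper_tail(k_eff, N, len(genes), n)
        tested.append((term, name, k, len(genes), p))
    adjusted = bh_adjust([t[4] for t in tested])
    results = [
        EnrichmentResult(term, name, k, K, n, N, p, p_adj, p_adj < alpha)
        for (term, name, k, K, p), p_adj in zip(tested, adjusted)
    ]
    results.sort(key=lambda r: (r.p_adj, r.term))
    return results


def write_enrichment(
    results: Sequence[EnrichmentResult], path: str | Path, header_note: str = ""
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        if header_note:
            fh.write(f"# {header_note}\n")
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["term", "term_name", "k", "K", "n", "N", "p_raw", "p_adj", "significant"]
        )
        for r in results:
            writer.writerow(
                [r.term, r.term_name, r.k, r.K, r.n, r.N, repr(r.p_raw), repr(r.p_adj), r.significant]
            )
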