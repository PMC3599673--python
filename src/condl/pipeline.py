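"""End-to-end pipeline: ingest → tag → paths → classify → networks → analysis.

`run_pipeline` wires every stage together, writes all intermediate and final
artifacts into a run directory, and logs the in/out counts of every
filtering stage as JSON so a run is auditable and reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import centrality as centrality_mod
from . import corpus as corpus_mod
from . import deppath as deppath_mod
from . import enrichment as enrichment_mod
from . import network as network_mod
from . import ner as ner_mod
from . import ontology as ontology_mod
from . import ppi as ppi_mod
from .classifier import (
    read_labeled_paths,
    save_model,
    score,
    train,
)
from .corpus import TermMatcher, VACCINE_VARIANTS

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All inputs and hyperparameters of a pipeline run."""

    corpus: Path
    lexicon: Path
    obo: Path
    keywords: Path
    conllu: Path
    labeled_paths: Path
    gmt: Path | None = None
    ppi: Path | None = None
    vaccine_root: str = "VO:0000001"
    vaccine_variants: tuple[str, ...] = VACCINE_VARIANTS
    gamma: float = 0.25
    C: float = 1.0
    threshold: float = 0.0
    k: int = 10
    alpha: float = 0.05
    enrichment_method: str = "ease"
    seed: int = 42

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("corpus", "lexicon", "obo", "keywords", "conllu", "labeled_paths"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config input {name}: {p} does not exist")
        for name in ("gmt", "ppi"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config input {name}: {p} does not exist")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Flat key = value text file; unknown keys rejected."""
        values: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        kwargs: dict = {}
        paths = {"corpus", "lexicon", "obo", "keywords", "conllu", "labeled_paths", "gmt", "ppi"}
        floats = {"gamma", "C", "threshold", "alpha"}
        ints = {"k", "seed"}
        for key, value in values.items():
            if key in paths:
                kwargs[key] = Path(value)
            elif key in floats:
                kwargs[key] = float(value)
            elif key in ints:
                kwargs[key] = int(value)
            elif key == "vaccine_root":
                kwargs[key] = value
            elif key == "vaccine_variants":
                kwargs[key] = tuple(v.strip() for v in value.split(",") if v.strip())
            elif key == "enrichment_method":
                kwargs[key] = value
            else:
                raise ValueError(f"{path}: unknown config key {key!r}")
        return cls(**kwargs)


@dataclass
class PipelineResult:
    run_dir: Path
    counts: dict
    networks: dict = field(default_factory=dict)
    comparison: centrality_mod.TopComparison | None = None
    enrichment: list = field(default_factory=list)
    overlap_counts: ppi_mod.OverlapCounts | None = None
    scored: list = field(default_factory=list)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_pipeline(config: PipelineConfig, run_dir: str | Path) -> PipelineResult:
    """Execute the full workflow and write all artifacts under ``run_dir``."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    counts: dict = {"config": {
        "gamma": config.gamma, "C": config.C, "threshold": config.threshold,
        "k": config.k, "alpha": config.alpha,
        "enrichment_method": config.enrichment_method, "seed": config.seed,
        "vaccine_root": config.vaccine_root,
        "vaccine_variants": list(config.vaccine_variants),
    }}

    # ingest
    docs = _stage("ingest")(corpus_mod.read_corpus)(config.corpus, "tsv")
    sentences = {}
    for doc in docs:
        for sent in corpus_mod.split_sentences(doc):
            sentences[(doc.doc_id, sent.sent_index)] = sent
    counts["documents"] = len(docs)
    counts["sentences"] = len(sentences)

    # tag
    lex = _stage("tag")(ner_mod.load_gene_lexicon)(config.lexicon)
    onto = _stage("tag")(ontology_mod.load_obo)(config.obo)
    vaccine_index = ner_mod.build_vaccine_index(onto, config.vaccine_root)
    mentions_by_sent = {}
    for key, sent in sentences.items():
        ms = ner_mod.tag_sentence(
            sent, lex, vaccine_variants=config.vaccine_variants,
            _vaccine_index=vaccine_index,
        )
        if ms:
            mentions_by_sent[key] = ms
    all_mentions = [m for ms in mentions_by_sent.values() for m in ms]
    ner_mod.write_mentions(all_mentions, run_dir / "mentions.tsv")
    counts["mentions"] = len(all_mentions)

    # candidates + dependency paths
    keywords = _stage("paths")(deppath_mod.load_keywords)(config.keywords)
    parses = {
        (p.doc_id, p.sent_index): p
        for p in _stage("paths")(deppath_mod.read_conllu)(config.conllu)
    }
    pairs_with_paths = []
    n_candidates = 0
    for key, ms in sorted(mentions_by_sent.items()):
        sent = sentences[key]
        cands = deppath_mod.find_candidates(sent, ms, keywords)
        n_candidates += len(cands)
        parse = parses.get(key)
        if parse is None:
            if cands:
                raise RuntimeError(
                    f"pipeline stage 'paths' failed: no parse for sentence {key}"
                )
            continue
        for cand in cands:
            others = [m for m in ms if m not in (cand.mention_a, cand.mention_b)]
            dep = deppath_mod.shortest_dep_path(
                parse, cand.mention_a, cand.mention_b, sent.text, others
            )
            pairs_with_paths.append((cand, dep))
    deppath_mod.write_paths(pairs_with_paths, run_dir / "paths.tsv")
    counts["candidates"] = n_candidates
    counts["paths"] = len(pairs_with_paths)

    # classify
    labeled = _stage("classify")(read_labeled_paths)(config.labeled_paths)
    model = _stage("classify")(train)(
        labeled, C=config.C, gamma=config.gamma, seed=config.seed
    )
    save_model(model, run_dir / "model.json")
    scored = [score(model, cand, dep) for cand, dep in pairs_with_paths]
    positives = [
        s for s in scored if s.score > config.threshold
    ]
    counts["positive_pairs"] = len(positives)
    with open(run_dir / "scored.tsv", "w", encoding="utf-8") as fh:
        fh.write("doc_id\tsent_index\tnorm_a\tnorm_b\tpair_kind\tscore\tis_positive\n")
        for s in scored:
            fh.write(
                f"{s.pair.doc_id}\t{s.pair.sent_index}\t{s.pair.mention_a.norm_id}\t"
                f"{s.pair.mention_b.norm_id}\t{s.pair.pair_kind}\t{s.score!r}\t"
                f"{s.score > config.threshold}\n"
            )

    # networks
    gg_scored = [s for s in scored if s.pair.pair_kind == "gene_gene"]
    full_net = network_mod.build_network(scored, config.threshold)
    gg_net = network_mod.build_network(gg_scored, config.threshold)
    variant_docs = {
        d.doc_id
        for d in corpus_mod.subset_corpus(docs, TermMatcher(config.vaccine_variants))
    }
    leaf_labels = [
        form
        for tid in sorted(ontology_mod.leaf_terms(onto, config.vaccine_root))
        for form in (onto.terms[tid].label, *onto.terms[tid].synonyms)
    ]
    vo_docs = {
        d.doc_id for d in corpus_mod.subset_corpus(docs, TermMatcher(leaf_labels))
    }
    vaccine_subset_docs = variant_docs | vo_docs
    sub_net = network_mod.subnetwork_by_corpus(
        gg_scored, vaccine_subset_docs, config.threshold
    )
    networks = {"full": full_net, "gene_gene": gg_net, "vaccine_subset": sub_net}
    for name, net in networks.items():
        network_mod.export_network(net, run_dir / f"network_{name}.graphml", "graphml")
        network_mod.export_network(net, run_dir / f"network_{name}.sif", "sif")
    counts["network_nodes"] = gg_net.number_of_nodes()
    counts["network_edges"] = gg_net.number_of_edges()
    counts["vaccine_subset_docs"] = len(vaccine_subset_docs)
    counts["vaccine_subset_edges"] = sub_net.number_of_edges()

    # centrality + top-k comparison
    comparison = None
    if gg_net.number_of_edges() and sub_net.number_of_edges():
        report_full = centrality_mod.compute_report(gg_net)
        report_sub = centrality_mod.compute_report(sub_net)
        centrality_mod.write_report(report_full, run_dir / "centrality_full.tsv")
        centrality_mod.write_report(report_sub, run_dir / "centrality_vaccine_subset.tsv")
        comparison = centrality_mod.write_comparison(
            report_full, report_sub, config.k, run_dir / "top_gene_comparison.tsv",
            label_a="full", label_b="vaccine_subset",
        )
        counts["top_genes_both"] = len(comparison.both)
        counts["top_genes_full_only"] = len(comparison.a_only)
        counts["top_genes_subset_only"] = len(comparison.b_only)

    # enrichment
    enrichment_results = []
    if config.gmt is not None:
        db = _stage("enrich")(enrichment_mod.load_gmt)(config.gmt)
        genes = sorted(
            n for n in gg_net.nodes if gg_net.nodes[n].get("ntype") == "gene"
        )
        if set(genes) & db.background:
            enrichment_results = enrichment_mod.enrich(
                genes, db, method=config.enrichment_method, alpha=config.alpha
            )
            enrichment_mod.write_enrichment(
                enrichment_results,
                run_dir / "enrichment.tsv",
                header_note=(
                    f"method={config.enrichment_method} alpha={config.alpha} "
                    f"background=all annotated genes (n={len(db.background)})"
                ),
            )
            counts["enriched_terms"] = sum(r.significant for r in enrichment_results)

    # PPI overlap
    overlap_counts = None
    if config.ppi is not None:
        ppi_edges, skipped = _stage("overlap")(ppi_mod.read_ppi)(config.ppi, lex)
        overlap_counts, merged = ppi_mod.overlap(full_net, ppi_edges)
        network_mod.export_network(merged, run_dir / "network_merged.graphml", "graphml")
        counts["ppi_rows_skipped"] = skipped
        counts["ppi_edges"] = len(ppi_edges)
        counts["overlap_both"] = overlap_counts.both
        counts["overlap_lit_only"] = overlap_counts.lit_only
        counts["overlap_ppi_only"] = overlap_counts.ppi_only

    (run_dir / "run_log.json").write_text(json.dumps(counts, indent=1, sort_keys=True))
    return PipelineResult(
        run_dir=run_dir,
        counts=counts,
        networks=networks,
        comparison=comparison,
        enrichment=enrichment_results,
        overlap_counts=overlap_counts,
        scored=scored,
    )
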