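"""Self-consistent synthetic fixture bundles with planted interactions.

The generator emulates every input the pipeline consumes: an abstract
corpus built from sentence templates, hand-authored dependency-parse
skeletons for those templates (one CoNLL-U block per sentence), a gene
lexicon with deliberately tricky synonyms, a small vaccine ontology whose
leaves are single-token strain names, an interaction-keyword list, a
separable labeled dependency-path training set, a PPI edge list and a GMT
annotation file.  Positive sentences instantiate interaction templates and
define the planted ground-truth edge set; negative sentences either lack an
interaction keyword or lack an entity pair, so candidate selection plus the
path classifier must recover exactly the planted edges.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from . import corpus as corpus_mod
from .classifier import LabeledPath, write_labeled_paths
from .deppath import DepParse, Token, write_conllu

__all__ = ["FixtureConfig", "FixtureBundle", "generate", "evaluate_extraction"]

# ---------------------------------------------------------------------------
# rosters

# (symbol, full name, synonyms).  Tricky entries on purpose: hyphen variants
# (IL-6), 2-character synonyms (T4), and the ambiguous synonym ERK shared by
# MAPK1 and MAPK3.
_GENE_ROSTER: list[tuple[str, str, list[str]]] = [
    ("IL6", "interleukin 6", ["IL-6", "BSF2"]),
    ("TNF", "tumor necrosis factor", ["TNF-alpha", "TNFA"]),
    ("IL1B", "interleukin 1 beta", ["IL-1B"]),
    ("IFNG", "interferon gamma", ["IFN-gamma"]),
    ("CD8A", "CD8 subunit alpha", ["CD8"]),
    ("CD4", "CD4 molecule", ["T4"]),
    ("IL10", "interleukin 10", ["IL-10"]),
    ("IL2", "interleukin 2", ["IL-2", "TCGF"]),
    ("CXCL8", "C-X-C motif chemokine ligand 8", ["IL8", "IL-8"]),
    ("NFKB1", "nuclear factor kappa B subunit 1", ["NF-kB1"]),
    ("MAPK1", "mitogen-activated protein kinase 1", ["ERK2", "ERK"]),
    ("MAPK3", "mitogen-activated protein kinase 3", ["ERK1", "ERK"]),
    ("HSPA1A", "heat shock protein family A member 1A", ["HSP70-1"]),
    ("POMC", "proopiomelanocortin", []),
    ("MEFV", "MEFV innate immunity regulator", ["pyrin"]),
    ("CSF2", "colony stimulating factor 2", ["GM-CSF"]),
    ("IL7R", "interleukin 7 receptor", ["IL-7R"]),
    ("APC", "APC regulator of WNT signaling", []),
    ("MC4R", "melanocortin 4 receptor", []),
    ("IL1R1", "interleukin 1 receptor type 1", ["IL-1R1"]),
    ("TLR2", "toll like receptor 2", []),
    ("TLR4", "toll like receptor 4", []),
    ("STAT3", "signal transducer and activator of transcription 3", []),
    ("IL1A", "interleukin 1 alpha", ["IL-1A"]),
    ("PTGES", "prostaglandin E synthase", []),
    ("PTGS2", "prostaglandin-endoperoxide synthase 2", ["COX-2", "COX2"]),
    ("LBP", "lipopolysaccharide binding protein", []),
    ("TNFRSF1A", "TNF receptor superfamily member 1A", ["TNFR1"]),
    ("TRAF1", "TNF receptor associated factor 1", []),
    ("CHUK", "component of inhibitor of kappa B kinase complex", ["IKK-alpha"]),
    ("HSP90AA1", "heat shock protein 90 alpha family class A member 1", []),
    ("VIPR1", "vasoactive intestinal peptide receptor 1", []),
]

# leaf vaccines: (term id, single-token label, synonym, parent key)
_VACCINE_LEAVES = [
    ("VO:0000101", "RB51", "Brucella abortus vaccine RB51", "bacterial"),
    ("VO:0000102", "SC602", "Shigella flexneri vaccine SC602", "bacterial"),
    ("VO:0000103", "WRSS1", "Shigella sonnei strain WRSS1", "bacterial"),
    ("VO:0000104", "WRSd1", "Shigella dysenteriae strain WRSd1", "bacterial"),
    ("VO:0000105", "BCG", "Bacillus Calmette-Guerin vaccine", "bacterial"),
    ("VO:0000106", "MMR", "measles mumps rubella vaccine", "viral"),
    ("VO:0000107", "IPV", "inactivated poliovirus vaccine", "viral"),
    ("VO:0000108", "OPV", "oral poliovirus vaccine", "viral"),
]

_GG_VERBS = [
    ("activate", "activates", "activated"),
    ("induce", "induces", "induced"),
    ("inhibit", "inhibits", "inhibited"),
    ("stimulate", "stimulates", "stimulated"),
    ("suppress", "suppresses", "suppressed"),
    ("regulate", "regulates", "regulated"),
    ("bind", "binds", None),  # irregular participle; active template only
]

_EXTRA_PATH_VERBS = ["mediate", "trigger", "block", "enhance", "promote", "modulate", "repress"]
_NEG_PATH_VERBS = [
    "measure", "observe", "detect", "report", "describe", "compare",
    "analyze", "include", "contain", "show", "find", "study", "examine", "assess",
]

# ---------------------------------------------------------------------------
# sentence templates: lists of (form, lemma, head, deprel)


def _active(a: str, verb3: str, lemma: str, b: str):
    return [
        (a, "_", 2, "nsubj"),
        (verb3, lemma, 0, "root"),
        (b, "_", 2, "obj"),
        (".", ".", 2, "punct"),
    ]


def _passive(a: str, participle: str, lemma: str, b: str):
    return [
        (a, "_", 3, "nsubj:pass"),
        ("was", "be", 3, "aux:pass"),
        (participle, lemma, 0, "root"),
        ("by", "by", 5, "case"),
        (b, "_", 3, "obl"),
        (".", ".", 3, "punct"),
    ]


def _relcl(a: str, verb3: str, lemma: str, b: str):
    return [
        (a, "_", 8, "nsubj"),
        (",", ",", 4, "punct"),
        ("which", "which", 4, "nsubj"),
        (verb3, lemma, 1, "acl:relcl"),
        (b, "_", 4, "obj"),
        (",", ",", 4, "punct"),
        ("was", "be", 8, "aux:pass"),
        ("elevated", "elevate", 0, "root"),
        (".", ".", 8, "punct"),
    ]


def _generic_vaccine(verb3: str, lemma: str, a: str):
    return [
        ("The", "the", 2, "det"),
        ("vaccine", "vaccine", 3, "nsubj"),
        (verb3, lemma, 0, "root"),
        (a, "_", 3, "obj"),
        (".", ".", 3, "punct"),
    ]


def _neg_cooccur(a: str, b: str, participle: str, lemma: str, place: str):
    return [
        (a, "_", 5, "nsubj"),
        ("and", "and", 3, "cc"),
        (b, "_", 1, "conj"),
        ("were", "be", 5, "aux"),
        (participle, lemma, 0, "root"),
        ("in", "in", 7, "case"),
        (place, place, 5, "obl"),
        (".", ".", 5, "punct"),
    ]


def _neg_single(a: str, verb3: str, lemma: str):
    return [
        (a, "_", 2, "nsubj"),
        (verb3, lemma, 0, "root"),
        ("inflammatory", "inflammatory", 4, "amod"),
        ("pathways", "pathway", 2, "obj"),
        (".", ".", 2, "punct"),
    ]


_NEG_PLAIN = [
    [
        ("Fever", "fever", 3, "nsubj"),
        ("was", "be", 3, "aux"),
        ("observed", "observe", 0, "root"),
        ("in", "in", 5, "case"),
        ("patients", "patient", 3, "obl"),
        (".", ".", 3, "punct"),
    ],
    [
        ("Temperature", "temperature", 3, "nsubj"),
        ("was", "be", 3, "aux"),
        ("recorded", "record", 0, "root"),
        ("daily", "daily", 3, "advmod"),
        (".", ".", 3, "punct"),
    ],
]


def _detokenize(tokens) -> str:
    text = ""
    for form, *_ in tokens:
        if text and form not in {".", ","}:
            text += " "
        text += form
    return text


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic bundle."""

    n_genes: int = 30
    n_vaccines: int = 5
    n_docs: int = 200
    sentences_per_doc: int = 3
    p_positive: float = 0.4
    seed: int = 42

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_vaccines, self.n_docs, self.sentences_per_doc) < 1:
            raise ValueError("all fixture counts must be >= 1")
        if not 0.0 <= self.p_positive <= 1.0:
            raise ValueError(f"p_positive must be in [0, 1], got {self.p_positive}")
        if self.n_genes > len(_GENE_ROSTER):
            raise ValueError(f"at most {len(_GENE_ROSTER)} genes available")
        if self.n_vaccines > len(_VACCINE_LEAVES):
            raise ValueError(f"at most {len(_VACCINE_LEAVES)} vaccines available")


@dataclass
class FixtureBundle:
    """File paths of a generated bundle plus its planted truth."""

    config: FixtureConfig
    corpus: Path
    conllu: Path
    lexicon: Path
    obo: Path
    keywords: Path
    labeled_paths: Path
    truth: Path
    ppi: Path
    gmt: Path
    truth_gene_gene: set[frozenset[str]] = field(default_factory=set)
    truth_gene_vaccine: set[frozenset[str]] = field(default_factory=set)


def _safe_surfaces(symbol: str, synonyms: list[str], all_entries) -> list[str]:
    """Surfaces usable in corpus slots: single-token forms that normalize
    back to exactly this symbol under the tagging rules."""
    surfaces = [symbol]
    claimed: dict[str, set[str]] = {}
    for sym, _, syns in all_entries:
        for s in syns:
            claimed.setdefault(s, set()).add(sym)
    for s in synonyms:
        if " " in s:
            continue
        if not (s[0].isupper() or s[0].isdigit()):
            continue  # slots can be sentence-initial; keep segmentation stable
        if len(claimed.get(s, set())) > 1:
            continue  # ambiguous synonym: tagger would drop it
        surfaces.append(s)
    return surfaces


def _write_lexicon(entries, path: Path) -> None:
    lines = ["symbol\tname\tsynonyms"]
    for sym, name, syns in entries:
        lines.append(f"{sym}\t{name}\t{'|'.join(syns)}")
    path.write_text("\n".join(lines) + "\n")


def _write_obo(leaves, path: Path) -> None:
    out = ["format-version: 1.2", "ontology: synthetic-vaccine-ontology", ""]

    def stanza(tid, name, parent=None, synonym=None):
        out.append("[Term]")
        out.append(f"id: {tid}")
        out.append(f"name: {name}")
        if synonym:
            out.append(f'synonym: "{synonym}" EXACT []')
        if parent:
            out.append(f"is_a: {parent[0]} ! {parent[1]}")
        out.append("")

    stanza("VO:0000001", "vaccine")
    groups = {g for _, _, _, g in leaves}
    if "bacterial" in groups:
        stanza("VO:0000010", "bacterial vaccine", ("VO:0000001", "vaccine"))
    if "viral" in groups:
        stanza("VO:0000011", "viral vaccine", ("VO:0000001", "vaccine"))
    parent_ids = {"bacterial": ("VO:0000010", "bacterial vaccine"),
                  "viral": ("VO:0000011", "viral vaccine")}
    for tid, label, synonym, group in leaves:
        stanza(tid, label, parent_ids[group], synonym)
    path.write_text("\n".join(out))


def _labeled_training_paths(rng: random.Random, n_per_class: int = 60) -> list[LabeledPath]:
    """A separable labeled-path set: interaction-verb path shapes vs.
    coordination/reporting path shapes."""
    verbs = [v[0] for v in _GG_VERBS] + _EXTRA_PATH_VERBS
    pos_shapes = [
        lambda v: ("ENTITYA", "nsubj<", v, "obj>", "ENTITYB"),
        lambda v: ("ENTITYA", "nsubj:pass<", v, "obl>", "ENTITYB"),
        lambda v: ("ENTITYA", "acl:relcl>", v, "obj>", "ENTITYB"),
        lambda v: ("ENTITYA", "obj<", v, "nsubj>", "ENTITYB"),
    ]
    neg_shapes = [
        lambda v: ("ENTITYA", "conj>", "ENTITYB"),
        lambda v: ("ENTITYA", "nsubj<", v, "conj>", "ENTITYB"),
        lambda v: ("ENTITYA", "nsubj<", v, "obl>", "ENTITYB"),
        lambda v: ("ENTITYA", "appos>", "ENTITYB"),
        lambda v: ("ENTITYA", "nmod<", "level", "nsubj<", v, "obl>", "ENTITYB"),
    ]
    labeled: list[LabeledPath] = []
    for n, shapes, verbset, label in (
        (n_per_class, pos_shapes, verbs, 1),
        (n_per_class, neg_shapes, _NEG_PATH_VERBS, -1),
    ):
        combos = [(s, v) for s in shapes for v in verbset]
        rng.shuffle(combos)
        while len(combos) < n:
            combos += combos
        for shape, verb in combos[:n]:
            labeled.append(LabeledPath(shape(verb), label))
    rng.shuffle(labeled)
    return labeled


def generate(config: FixtureConfig, out_dir: str | Path) -> FixtureBundle:
    """Write a complete fixture bundle under ``out_dir``; deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(config.seed)

    entries = _GENE_ROSTER[: config.n_genes]
    leaves = _VACCINE_LEAVES[: config.n_vaccines]
    surfaces = {sym: _safe_surfaces(sym, syns, entries) for sym, _, syns in entries}
    symbols = [sym for sym, _, _ in entries]

    docs: list[corpus_mod.DocumentRecord] = []
    parses: list[DepParse] = []
    truth_gg: set[frozenset[str]] = set()
    truth_gv: set[frozenset[str]] = set()

    def pick_surface(sym: str) -> str:
        forms = surfaces[sym]
        if len(forms) > 1 and rng.random() < 0.2:
            return rng.choice(forms[1:])
        return forms[0]

    for d in range(config.n_docs):
        doc_id = f"SYN{d + 1:04d}"
        sent_tokens = []
        for _ in range(config.sentences_per_doc):
            if rng.random() < config.p_positive:
                kind = rng.choices(
                    ["gg", "gv_specific", "gv_general"], weights=[0.6, 0.25, 0.15]
                )[0]
                if kind == "gg":
                    a, b = rng.sample(symbols, 2)
                    lemma, v3, ved = rng.choice(_GG_VERBS)
                    shape = rng.choice(["active", "passive", "relcl"])
                    if ved is None and shape == "passive":
                        shape = "active"
                    sa, sb = pick_surface(a), pick_surface(b)
                    if shape == "active":
                        toks = _active(sa, v3, lemma, sb)
                    elif shape == "passive":
                        toks = _passive(sa, ved, lemma, sb)
                    else:
                        toks = _relcl(sa, v3, lemma, sb)
                    truth_gg.add(frozenset((a, b)))
                elif kind == "gv_specific":
                    g = rng.choice(symbols)
                    tid, label, _, _ = rng.choice(leaves)
                    lemma, v3, ved = rng.choice(_GG_VERBS[:6])
                    if rng.random() < 0.5:
                        toks = _active(label, v3, lemma, pick_surface(g))
                    else:
                        toks = _passive(pick_surface(g), ved, lemma, label)
                    truth_gv.add(frozenset((g, tid)))
                else:
                    g = rng.choice(symbols)
                    lemma, v3, _ = rng.choice(_GG_VERBS[:6])
                    toks = _generic_vaccine(v3, lemma, pick_surface(g))
                    truth_gv.add(frozenset((g, "vaccine")))
            else:
                kind = rng.choices(["cooccur", "single", "plain"], weights=[0.4, 0.3, 0.3])[0]
                if kind == "cooccur":
                    a, b = rng.sample(symbols, 2)
                    lemma = rng.choice(["measure", "detect", "observe"])
                    place = rng.choice(["serum", "plasma", "patients"])
                    toks = _neg_cooccur(
                        pick_surface(a), pick_surface(b), lemma + "d", lemma, place
                    )
                elif kind == "single":
                    g = rng.choice(symbols)
                    lemma, v3, _ = rng.choice(_GG_VERBS[:6])
                    toks = _neg_single(pick_surface(g), v3, lemma)
                else:
                    toks = rng.choice(_NEG_PLAIN)
            sent_tokens.append(toks)

        abstract = " ".join(_detokenize(t) for t in sent_tokens)
        doc = corpus_mod.DocumentRecord(doc_id, "", abstract)
        docs.append(doc)
        sentences = corpus_mod.split_sentences(doc)
        if len(sentences) != len(sent_tokens):
            raise RuntimeError(
                f"{doc_id}: template sentences do not survive segmentation "
                f"({len(sentences)} != {len(sent_tokens)})"
            )
        for sent, toks in zip(sentences, sent_tokens):
            parses.append(
                DepParse(
                    doc_id,
                    sent.sent_index,
                    tuple(
                        Token(i + 1, form, lemma, head, deprel)
                        for i, (form, lemma, head, deprel) in enumerate(toks)
                    ),
                )
            )

    bundle = FixtureBundle(
        config=config,
        corpus=out / "corpus.tsv",
        conllu=out / "parses.conllu",
        lexicon=out / "genes.tsv",
        obo=out / "vaccines.obo",
        keywords=out / "keywords.txt",
        labeled_paths=out / "labeled_paths.tsv",
        truth=out / "truth_edges.tsv",
        ppi=out / "ppi.tsv",
        gmt=out / "annotations.gmt",
        truth_gene_gene=truth_gg,
        truth_gene_vaccine=truth_gv,
    )

    corpus_mod.write_corpus(docs, bundle.corpus)
    write_conllu(parses, bundle.conllu)
    _write_lexicon(entries, bundle.lexicon)
    _write_obo(leaves, bundle.obo)

    from importlib import resources

    bundle.keywords.write_text(
        resources.files("condl.data").joinpath("keywords.txt").read_text()
    )
    write_labeled_paths(_labeled_training_paths(rng), bundle.labeled_paths)

    with open(bundle.truth, "w", encoding="utf-8") as fh:
        fh.write("node_a\tnode_b\tkind\n")
        for pair in sorted(map(sorted, truth_gg)):
            fh.write(f"{pair[0]}\t{pair[1]}\tgene_gene\n")
        for pair in sorted(map(sorted, truth_gv)):
            fh.write(f"{pair[0]}\t{pair[1]}\tgene_vaccine\n")

    # PPI list: some planted edges (shared with the literature network), some
    # PPI-only edges, plus rows the reader must clean up.
    shared = sorted(map(sorted, truth_gg))[: max(3, len(truth_gg) // 4)]
    ppi_rows = [tuple(p) for p in shared]
    for _ in range(15):
        a, b = rng.sample(symbols, 2)
        if frozenset((a, b)) not in truth_gg:
            ppi_rows.append((a, b))
    with open(bundle.ppi, "w", encoding="utf-8") as fh:
        for a, b in ppi_rows:
            fh.write(f"{a}\t{b}\n")
        if ppi_rows:
            a, b = ppi_rows[0]
            fh.write(f"{b}\t{a}\n")  # reciprocal duplicate
        fh.write(f"{symbols[0]}\t{symbols[0]}\n")  # self-interaction
        fh.write(f"UNKNOWN999\t{symbols[0]}\n")  # unmappable symbol

    categories = {
        "SYN:0001\tinflammatory response": [
            "IL6", "TNF", "IL1B", "IL1A", "IL10", "IL2", "CXCL8", "IFNG", "CSF2", "LBP",
        ],
        "SYN:0002\tsignal transduction": [
            "MAPK1", "MAPK3", "STAT3", "NFKB1", "CHUK", "TRAF1", "POMC", "MEFV",
        ],
        "SYN:0003\treceptor activity": [
            "IL7R", "IL1R1", "TLR2", "TLR4", "MC4R", "CD4", "CD8A", "TNFRSF1A", "VIPR1",
        ],
        "SYN:0004\tstress and prostaglandin synthesis": [
            "PTGES", "PTGS2", "HSPA1A", "HSP90AA1", "APC",
        ],
    }
    with open(bundle.gmt, "w", encoding="utf-8") as fh:
        for head, genes in categories.items():
            members = [g for g in genes if g in set(symbols)]
            if len(members) >= 2:
                fh.write(head + "\t" + "\t".join(members) + "\n")

    return bundle


def evaluate_extraction(
    predicted: set[frozenset[str]], truth: set[frozenset[str]]
) -> tuple[float, float, float]:
    """Set-based precision/recall/F1 over unordered entity pairs.

    Conventions for empty denominators: with no predictions and no truth all
    three are 1.0; predictions against an empty truth give precision 0.0.
    """
    if not predicted and not truth:
        return 1.0, 1.0, 1.0
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth) if truth else 0.0
    if precision + recall == 0:
        return precision, recall, 0.0
    return precision, recall, 2 * precision * recall / (precision + recall)
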