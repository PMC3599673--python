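# Methods

## Overview

condl extracts interaction networks from abstract text in five stages:
sentence segmentation, dictionary/ontology-based entity tagging, candidate
filtering by interaction keywords, dependency-path classification with an
edit-distance-kernel SVM, and network assembly with downstream centrality,
enrichment and PPI-overlap analysis. This note records the models,
parameter defaults, numerical choices and the open design decisions we
resolved, and what the synthetic evaluation does and does not demonstrate.

## Sentence segmentation

Sentences end at `.?!` followed by whitespace and an uppercase letter or
digit; a configurable abbreviation list ("E.", "sp.", "et al.", "Fig.",
"vs." by default) suppresses false boundaries. The title is one sentence
unless it contains sentence-final punctuation itself; title sentences
precede abstract sentences in the 0-based sentence index. Offsets are
0-based half-open into `title + "\n" + abstract`, and every sentence's
span slices the source to exactly its text. This splitter is deliberately
rule-based and dependency-free so that segmentation is a stable, auditable
part of the pipeline rather than a model artifact.

## Entity tagging

Gene tagging is dictionary-based over a TSV lexicon (official symbol, full
name, pipe-separated synonyms). Lookup forms are normalized by mapping
Greek letters to their spelled-out names, lowercasing and collapsing
hyphen/whitespace runs; every form is also indexed with internal
separators removed, so `IL-6` and `IL6` are interchangeable. Three rules
control precision:

* surfaces of ≤ 2 characters must match an indexed form case-sensitively
  (otherwise "as", "in", "T4" as a word, … would all tag);
* a surface mapping to more than one official symbol is dropped unless it
  *is* one of those symbols verbatim (precision-first disambiguation);
* matches start and end at alphanumeric token boundaries, and scanning is
  longest-match-wins, left to right, so "BCG vaccine" absorbs the generic
  word "vaccine".

Specific vaccine names come from an OBO ontology: the tagging dictionary
is the set of **leaf terms** under the configured root ("vaccine"), i.e.
descendants with no children — the most specific vaccine names the
hierarchy knows. Ancestor sets are reflexive-free transitive closures over
`is_a`; the loader rejects cycles and dangling parents and skips obsolete
terms. Only the asserted `is_a` hierarchy is used; OWL-style logical
definitions and inferred classifications are out of scope. Generic vaccine
mentions are matched against a configurable surface-variant list
(vaccine/vaccines/vaccination/…) and normalized to the single node id
`vaccine`.

## Candidate pairs and dependency paths

A sentence yields candidate pairs only if it contains an interaction
keyword. The packaged keyword list (~60 stems, user-replaceable) is
matched case-insensitively at token boundaries after light stemming: the
suffixes `-s, -es, -d, -ed, -ing` are stripped when the remaining stem has
at least 4 characters, so "binds", "binding" and "induced" all hit their
stems. Pairs are unordered, require distinct normalized ids, and are
either gene–gene or gene–vaccine; vaccine–vaccine pairs are not extracted.

Dependency parses are consumed as CoNLL-U (the package does not parse;
any UD-style parser can feed it — the reader is a small built-in since
no CoNLL-U library is a dependency). Each mention is aligned to its head
token: the overlapped token whose syntactic head lies outside the mention,
else the rightmost overlapped token (head-final bias of English noun
phrases). The path between the two head tokens in the undirected
dependency tree is unique; it is serialized as alternating node/edge
tokens where nodes are lowercased lemmas (form fallback when the lemma
column is `_`), the endpoints become `ENTITYA`/`ENTITYB`, other tagged
entities on the path become `ENTITYX`, and each relation carries a
traversal direction marker (`<` toward the head, `>` toward the
dependent). Mentions aligning to the same token are rejected as degenerate
pairs.

## Path classification

The classifier is a soft-margin SVM over path sequences with the kernel
`K(x, y) = exp(−γ · d(x, y))`, `d` being word-level Levenshtein distance
(unit insert/delete/substitute over whole tokens). Defaults: γ = 0.25,
C = 1.0 — a bounded, similarity-decaying kernel with a single decay
hyperparameter. Edit-distance kernels are not guaranteed positive
semidefinite, so the training Gram matrix is repaired by clipping negative
eigenvalues (flagged when it happens, tolerance 1e−9); test-time decision
values always use the raw kernel against the support paths. The decision
threshold is fixed at 0 — positive decision values define interactions —
and is exposed as an explicit `--threshold` flag rather than a hidden
tunable. The dual solver is scikit-learn's SVC on the precomputed
(repaired) Gram matrix; with fixed data order the fit is deterministic.

## Networks

Networks are simple undirected graphs: nodes are genes (official symbols)
or vaccines (ontology term ids, plus the single generic `vaccine` node);
edges carry the set of supporting `(doc_id, sentence)` evidence, its count
and the maximum SVM score seen. Repeated sentence-level detections of a
pair merge into one edge; self-pairs are dropped. Edges are undirected —
keywords include directional relations but the extracted unit is "an
interaction was described", with direction recoverable from evidence
sentences. Subset networks are built by filtering evidence to a document
subset (e.g. vaccine-related articles), so a subset network's edges are
always a subset of the full network's. Exports: SIF and GraphML
(Cytoscape-compatible; GraphML round-trips exactly) and an attribute TSV.

## Centrality and top-k comparison

Four measures per node: raw degree; eigenvector centrality; closeness with
the Wasserman–Faust component correction
`((n_c − 1)/Σd) · ((n_c − 1)/(N − 1))` (literature networks are routinely
disconnected, isolated nodes score 0); and unnormalized Brandes
betweenness (endpoints excluded, unordered pairs counted once — only
ranks are consumed downstream). Eigenvector centrality is power iteration
with a uniform positive start and L2 normalization, converged when the L2
gap between successive iterates drops below 1e−10; the iteration runs on
`A + I` because the shift leaves the dominant eigenvector unchanged while
guaranteeing convergence on bipartite graphs, where pure adjacency
iteration oscillates between the ±λ_max eigenspaces. Ranking is
competition ranking on descending score with ties broken by node id, so
reports are fully deterministic; vaccine nodes are excluded from gene
rankings by default (they still contribute to gene scores through the
graph). Two networks are compared by the sets of genes in the top *k*
(default 10) by **at least one** measure: shared, A-only and B-only
groups.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) with background N = all genes annotated in the GMT file (unless
an explicit universe is given — the choice is logged in the output
header). The default method is the EASE variant, which replaces k by
k − 1 — the conservative "modified Fisher's exact test" used by common
enrichment servers — and terms overlapping the query by fewer than 2
genes are skipped, mirroring those servers' default filtering.
Benjamini–Hochberg step-up adjustment is applied across all tested terms
with significance at adjusted p < 0.05.

## PPI overlap and indirect hypotheses

The external PPI edge list is lexicon-normalized, deduplicated and
stripped of self-interactions; rows with unmappable symbols are counted
and skipped. By default PPI edges are restricted to pairs among the
literature network's genes before comparison: the question asked is "how
many of the literature interactions are known physical interactions among
these same genes". Merged edges are tagged `literature` / `ppi` / `both`,
a partition of the merged edge set. Around a shared anchor edge (a, b),
every pairing of a literature-only gene partner of a with a PPI-only gene
partner of b (and symmetrically) yields an indirect-interaction
hypothesis x–a–b–y, with all four nodes distinct.

## Synthetic data and what the tests show

The generator emulates every pipeline input with one coherent bundle:
corpus TSV, one hand-authored CoNLL-U parse per sentence, gene lexicon,
vaccine ontology, keyword list, labeled training paths, planted truth
edges, PPI list and GMT file. Default study conditions: 200 documents ×
3 sentences, 30 genes, 5 single-token leaf vaccines, 40% of sentences
drawn from interaction templates (six template families: active, passive
and relative-clause gene–gene forms, specific- and generic-vaccine forms),
the remainder from negative templates that either lack an interaction
keyword or lack an entity pair. Interaction pairs are sampled uniformly;
the planted truth is the set of pairs used in positive templates. The
labeled training set (n = 120, balanced) pairs interaction-verb path
shapes against coordination/reporting path shapes and is separable by
design. Lexicon surfaces are deliberately tricky (hyphen variants, a
2-character synonym, one ambiguous synonym shared by two genes) to
exercise the tagging rules; documents carry empty titles so the corpus
has exactly `n_docs × sentences_per_doc` sentences.

Parses are template-level skeletons, not parser output: this keeps the
bundle deterministic (same seed ⇒ byte-identical files) and the truth
exactly recoverable. Consequently, passing the end-to-end test (planted
gene–gene F1 ≥ 0.9, gene–vaccine F1 ≥ 0.8) demonstrates that the
machinery — tagging rules, keyword filter, path extraction, kernel SVM,
network assembly — is correct and deterministic; it does **not**
demonstrate performance on real PubMed language, which has parser noise,
anaphora, nested entities and far more varied syntax. Similarly, because
interaction pairs are sampled uniformly over the gene roster, the
synthetic enrichment analysis correctly finds nothing significant; the
enrichment statistics themselves are validated against exact
combinatorial enumeration instead.

Corpus-scale properties of the original application domain (hundreds of
thousands of articles, database-dependent gene counts and enrichment
scores) depend on external snapshots and services and are out of scope;
the package reproduces the procedures, and all quantitative checks run on
the synthetic conditions above. Problem sizes used by the test suite and
acceptance script (random-graph oracles at n ≤ 8–12 with 100–500 trials,
the 200-document bundle) were chosen as the smallest sizes at which the
checked properties are non-trivial.

## Numerical and degenerate-input choices

* Edit distance: iterative two-row DP; empty sequences allowed.
* Gram repair: `eigh`, clip eigenvalues below 0, reconstruct, re-symmetrize.
* Power iteration: max 10 000 iterations; failure reports the last iterate
  gap. Edgeless graphs are an error for eigenvector centrality (the
  measure is undefined), not a silent zero.
* Empty-denominator conventions for precision/recall: no predictions and
  no truth → 1.0; predictions against empty truth → precision 0.
* BH on an empty vector returns an empty vector; p-values outside [0, 1]
  are an error.
* Duplicate document ids, duplicate official symbols, ontology cycles and
  dangling parents, malformed CoNLL-U (missing root, dangling head) are
  all hard errors that name the offending location.

## Known limitations

* No abbreviation-definition detection ("tumor necrosis factor (TNF)"),
  no coreference, no cross-sentence pairs.
* One interaction keyword qualifies the whole sentence; the keyword is not
  required to lie on the dependency path.
* The kernel ignores token content beyond exact identity (no similarity
  between "activate" and "stimulate"); a synonym-aware kernel would be a
  drop-in extension point.
* The single generic `vaccine` node aggregates all non-specific vaccine
  mentions.
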