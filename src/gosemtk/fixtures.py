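"""Deterministic synthetic fixtures.

Everything the toolkit consumes can be generated here without downloads:
two hand-checkable toy ontologies with annotation corpora, seeded random
DAGs and trees for property testing, and benchmark table bundles with
planted structure for the statistical harness.  Every generator is a
pure function of its arguments (seed included); regeneration is
byte-identical.  The random graphs aim only for single-rootedness and
DAG-ness, not for realistic GO topology statistics.

Planted-structure scenarios (documented effect sizes, chosen once):

``ppi_signal``
    8 functional modules x 8 genes on an ~80-term DAG.  Genes of one
    module annotate a shared anchor term plus a private leaf below it, so
    within-module pairs (label 1) have high best-match-average ancestor
    overlap while cross-module pairs (label 0) share little beyond the
    root.  Reference tables carry matched signal: reciprocal bit scores
    0.55-0.95 of the self score for interacting pairs vs 0.02-0.25
    otherwise; two module-specific domains per gene plus one ubiquitous
    housekeeping domain; expression profiles = module latent profile +
    N(0, 0.5) noise over 20 conditions.

``pathways``
    3 pathways x 10 genes; each pathway owns a branch of the ontology
    and its genes annotate two terms inside that branch, so semantic
    distances separate the pathways cleanly for Ward clustering.

``multiview``
    600 labeled pairs with per-namespace latent signals v_BP, v_MF,
    v_CC ~ N(0,1); the label is 1 iff a majority of the three views is
    positive, so no single view determines the class.  Each
    namespace contributes 3 score columns v_ns + eta_ns + eps with
    shared within-namespace noise eta_ns ~ N(0, 0.4) and tiny
    independent jitter eps ~ N(0, 0.005).  Columns within one namespace
    therefore carry the same partial information, while the three
    namespaces are independently informative — the regime where voting
    across namespaces helps but voting within one cannot.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import AnnotationCorpus, write_gaf
from .errors import ValidationError
from .evaluation import PairScoreTable, Partition
from .ontology import OntologyGraph, Term, write_obo
from .reference import BitScoreTable, DomainCorpus, ExpressionMatrix

_NS_PREFIX = {"BP": "biological_process", "MF": "molecular_function", "CC": "cellular_component"}


def _mk_terms(ids, namespace):
    return [Term(id=i, name=i.lower(), namespace=namespace) for i in ids]


def toy1() -> tuple[OntologyGraph, AnnotationCorpus]:
    """Seven-term diamond DAG used for all worked examples.

    Edges (child -> parent): A->R, B->R, C->A, C->B, D->A, E->C, F->C,
    F->D; corpus (g1,E), (g2,F), (g3,D), (g4,B).  Base-2 IC:
    R=0, A=B=log2(4/3), C=D=1, E=F=2 bits.
    """
    edges = [("A", "R"), ("B", "R"), ("C", "A"), ("C", "B"),
             ("D", "A"), ("E", "C"), ("F", "C"), ("F", "D")]
    g = OntologyGraph(
        _mk_terms("RABCDEF", "BP"), [(c, p, "is_a") for c, p in edges]
    )
    corpus = AnnotationCorpus()
    for gene, term in [("g1", "E"), ("g2", "F"), ("g3", "D"), ("g4", "B")]:
        corpus.add(gene, term, "BP")
    return g, corpus


def toy2() -> tuple[OntologyGraph, AnnotationCorpus]:
    """Four-term tree separating GraSM's >= rule from A-GraSM's >.

    Edges A->R, B->A, D->A; corpus (g1,B), (g2,D), (g3,A), (g4,R).
    For (B, D): both common ancestors A and R have summed path count 2,
    so GraSM admits both (mean IC) while A-GraSM keeps only A (= MICA).
    """
    g = OntologyGraph(
        _mk_terms("RABD", "BP"),
        [("A", "R", "is_a"), ("B", "A", "is_a"), ("D", "A", "is_a")],
    )
    corpus = AnnotationCorpus()
    for gene, term in [("g1", "B"), ("g2", "D"), ("g3", "A"), ("g4", "R")]:
        corpus.add(gene, term, "BP")
    return g, corpus


def random_dag(
    n_terms: int, mean_parents: float = 1.5, seed: int = 0, namespace: str = "BP"
) -> OntologyGraph:
    """Seeded single-rooted random DAG.

    Terms are created in order; each new term attaches to 1 + a Poisson
    draw (mean ``mean_parents`` - 1) of distinct earlier terms, so edges
    always point from newer (more specific) to older (more general)
    terms and acyclicity and single-rootedness hold by construction.
    """
    if n_terms < 1 or mean_parents < 1:
        raise ValidationError("need n_terms >= 1 and mean_parents >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"{namespace}T{i:04d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_par = min(i, 1 + rng.poisson(mean_parents - 1.0))
        parents = rng.choice(i, size=n_par, replace=False)
        edges.extend((ids[i], ids[int(p)], "is_a") for p in sorted(parents))
    return OntologyGraph(_mk_terms(ids, namespace), edges)


def random_tree(n_terms: int, seed: int = 0, namespace: str = "BP") -> OntologyGraph:
    """Seeded random rooted tree: exactly one parent per non-root term."""
    if n_terms < 1:
        raise ValidationError("need n_terms >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"{namespace}T{i:04d}" for i in range(n_terms)]
    edges = [
        (ids[i], ids[int(rng.integers(0, i))], "is_a") for i in range(1, n_terms)
    ]
    return OntologyGraph(_mk_terms(ids, namespace), edges)


def random_corpus(
    g: OntologyGraph,
    n_genes: int,
    seed: int = 0,
    max_terms_per_gene: int = 3,
) -> AnnotationCorpus:
    """Seeded random corpus: each gene annotates 1..max_terms_per_gene
    distinct terms drawn uniformly from the graph."""
    rng = np.random.default_rng(seed)
    terms = g.terms()
    corpus = AnnotationCorpus()
    for i in range(n_genes):
        k = int(rng.integers(1, max_terms_per_gene + 1))
        for t in rng.choice(len(terms), size=min(k, len(terms)), replace=False):
            corpus.add(f"g{i:04d}", terms[int(t)], g.namespace)
    return corpus


# -- planted benchmark bundles ---------------------------------------------

@dataclass
class BenchmarkTables:
    """Everything one scenario emits; fields unused by a scenario are None."""

    scenario: str
    seed: int
    pairs: PairScoreTable
    graphs: dict[str, OntologyGraph] | None = None
    corpus: AnnotationCorpus | None = None
    bitscores: BitScoreTable | None = None
    domains: DomainCorpus | None = None
    expression: ExpressionMatrix | None = None
    pathways: Partition | None = None

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pairs.data.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        if self.graphs:
            write_obo(self.graphs, outdir / "ontology.obo")
        if self.corpus:
            write_gaf(self.corpus, outdir / "annotations.gaf")
        if self.bitscores:
            self.bitscores.write_tsv(outdir / "bitscores.tsv")
        if self.domains:
            self.domains.write_tsv(outdir / "domains.tsv")
        if self.expression:
            self.expression.write_tsv(outdir / "expression.tsv")
        if self.pathways:
            rows = [f"{g}\t{c}" for g, c in sorted(self.pathways.labels.items())]
            (outdir / "pathways.tsv").write_text("\n".join(rows) + "\n")


def _module_ontology(
    n_modules: int, genes_per_module: int, namespace: str = "BP"
) -> tuple[OntologyGraph, AnnotationCorpus, dict[str, int]]:
    """Root -> per-module branch -> anchor -> per-gene leaf; genes annotate
    their private leaf and the module anchor.  Anchors get a second parent
    (the next module's branch) so the graph is a true DAG, not a tree."""
    ids = ["R"] + [f"HK{j}" for j in range(2)]
    edges = [(f"HK{j}", "R", "is_a") for j in range(2)]
    corpus = AnnotationCorpus()
    membership: dict[str, int] = {}
    for mod in range(n_modules):
        branch, anchor = f"B{mod:02d}", f"A{mod:02d}"
        ids += [branch, anchor]
        edges.append((branch, "R", "is_a"))
        edges.append((anchor, branch, "is_a"))
        # cross edge: anchor also part_of the neighbouring branch
        edges.append((anchor, f"B{(mod + 1) % n_modules:02d}", "part_of"))
        for j in range(genes_per_module):
            leaf, gene = f"L{mod:02d}_{j}", f"gene{mod:02d}_{j}"
            ids.append(leaf)
            edges.append((leaf, anchor, "is_a"))
            corpus.add(gene, leaf, namespace)
            corpus.add(gene, anchor, namespace)
            membership[gene] = mod
    # fix forward references: neighbour branches exist only after the loop,
    # so ids are complete here; build graph once
    g = OntologyGraph(_mk_terms(ids, namespace), edges)
    return g, corpus, membership


def _ppi_signal(seed: int, n_modules: int = 8, genes_per_module: int = 8,
                n_conditions: int = 20) -> BenchmarkTables:
    rng = np.random.default_rng(seed)
    g, corpus, membership = _module_ontology(n_modules, genes_per_module)
    genes = sorted(membership)
    # housekeeping annotations add corpus-wide noise terms
    for gene in genes:
        if rng.random() < 0.3:
            corpus.add(gene, f"HK{int(rng.integers(0, 2))}", "BP")

    positives = [
        (a, b)
        for a in genes
        for b in genes
        if a < b and membership[a] == membership[b]
    ]
    cross = [
        (a, b)
        for a in genes
        for b in genes
        if a < b and membership[a] != membership[b]
    ]
    neg_idx = rng.choice(len(cross), size=len(positives), replace=False)
    negatives = [cross[int(i)] for i in sorted(neg_idx)]
    rows = [(a, b, 1) for a, b in positives] + [(a, b, 0) for a, b in negatives]
    pairs = PairScoreTable(pd.DataFrame(rows, columns=["id1", "id2", "label"]))

    bits = BitScoreTable()
    selves = {gene: float(rng.uniform(150, 250)) for gene in genes}
    for gene, s in selves.items():
        bits.add(gene, gene, s)
    for a, b, label in rows:
        frac = rng.uniform(0.55, 0.95) if label else rng.uniform(0.02, 0.25)
        cross_score = float(frac * min(selves[a], selves[b]))
        bits.add(a, b, cross_score)
        bits.add(b, a, cross_score * float(rng.uniform(0.95, 1.05)))

    domains = DomainCorpus()
    for gene in genes:
        mod = membership[gene]
        domains.add(gene, f"PF_mod{mod:02d}a")
        domains.add(gene, f"PF_mod{mod:02d}b")
        domains.add(gene, f"PF_hk{int(rng.integers(0, 3))}")

    latent = rng.normal(0.0, 1.0, size=(n_modules, n_conditions))
    profiles = {
        gene: latent[membership[gene]] + rng.normal(0.0, 0.5, size=n_conditions)
        for gene in genes
    }
    expression = ExpressionMatrix(
        pd.DataFrame.from_dict(profiles, orient="index",
                               columns=[f"c{j}" for j in range(n_conditions)])
    )
    return BenchmarkTables(
        scenario="ppi_signal", seed=seed, pairs=pairs, graphs={"BP": g},
        corpus=corpus, bitscores=bits, domains=domains, expression=expression,
        pathways=Partition(dict(membership)),
    )


def _pathways(seed: int, n_pathways: int = 3, genes_per_pathway: int = 10,
              terms_per_branch: int = 4) -> BenchmarkTables:
    rng = np.random.default_rng(seed)
    ids, edges = ["R"], []
    corpus = AnnotationCorpus()
    truth: dict[str, int] = {}
    for p in range(n_pathways):
        branch = f"B{p:02d}"
        ids.append(branch)
        edges.append((branch, "R", "is_a"))
        subs = [f"S{p:02d}_{j}" for j in range(terms_per_branch)]
        for s in subs:
            ids.append(s)
            edges.append((s, branch, "is_a"))
        for j in range(genes_per_pathway):
            gene = f"gene{p:02d}_{j}"
            truth[gene] = p
            for s in rng.choice(terms_per_branch, size=2, replace=False):
                corpus.add(gene, subs[int(s)], "BP")
    g = OntologyGraph(_mk_terms(ids, "BP"), edges)
    genes = sorted(truth)
    rows = [(a, b, 1 if truth[a] == truth[b] else 0)
            for i, a in enumerate(genes) for b in genes[i + 1:]]
    pairs = PairScoreTable(pd.DataFrame(rows, columns=["id1", "id2", "label"]))
    return BenchmarkTables(
        scenario="pathways", seed=seed, pairs=pairs, graphs={"BP": g},
        corpus=corpus, pathways=Partition(truth),
    )


def _multiview(seed: int, n_pairs: int = 600, measures_per_ns: int = 3,
               shared_noise_sd: float = 0.4, jitter_sd: float = 0.005) -> BenchmarkTables:
    rng = np.random.default_rng(seed)
    views = {ns: rng.normal(0.0, 1.0, size=n_pairs) for ns in ("BP", "MF", "CC")}
    positive_views = sum((v > 0).astype(int) for v in views.values())
    labels = (positive_views >= 2).astype(int)
    data = {
        "id1": [f"pA{i:04d}" for i in range(n_pairs)],
        "id2": [f"pB{i:04d}" for i in range(n_pairs)],
        "label": labels,
    }
    for ns in ("BP", "MF", "CC"):
        eta = rng.normal(0.0, shared_noise_sd, size=n_pairs)
        for j in range(measures_per_ns):
            eps = rng.normal(0.0, jitter_sd, size=n_pairs)
            data[f"{ns}:m{j}"] = views[ns] + eta + eps
    return BenchmarkTables(
        scenario="multiview", seed=seed,
        pairs=PairScoreTable(pd.DataFrame(data)),
    )


_SCENARIOS = {"ppi_signal": _ppi_signal, "pathways": _pathways, "multiview": _multiview}


def synthetic_benchmark_tables(
    scenario: str = "ppi_signal", seed: int = 0, **size_params
) -> BenchmarkTables:
    """Generate one planted-structure benchmark bundle (see module docs)."""
    try:
        factory = _SCENARIOS[scenario]
    except KeyError:
        raise ValidationError(
            f"unknown scenario {scenario!r}; expected one of {sorted(_SCENARIOS)}"
        ) from None
    return factory(seed, **size_params)
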