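"""Gene-level functional similarity.

Two routes from term similarity to gene similarity:

* aggregation of the all-pairs term-similarity table between two genes'
  annotation sets (max, average, or best-match average);
* Jaccard-family measures acting directly on the genes' reflexive
  ancestor closures, optionally IC-weighted (SimUI, SimGIC, SimDIC,
  SimUIC).

A gene's profile in a namespace is its directly annotated term set plus
the union of those terms' reflexive ancestor sets (the induced rootward
subgraph).  Genes without annotations in a namespace are undefined there
and callers drop such pairs with a count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

from .annotations import AnnotationCorpus
from .errors import DomainError, ValidationError
from .infocontent import ICTable
from .ontology import NAMESPACES, OntologyGraph
from .shared_info import SI_METHODS
from .termsim import SS_METHODS

AGGREGATORS = ("max", "avg", "bma")
JACCARD_MEASURES = ("simui", "simgic", "simdic", "simuic")


@dataclass(frozen=True)
class GeneProfile:
    """One gene's annotation profile in a single namespace."""

    gene: str
    terms: frozenset[str]
    closure: frozenset[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise DomainError(f"gene {self.gene!r} has no annotated terms")
        if not self.terms <= self.closure:
            raise ValidationError("ancestor closure must contain the annotated terms")


def gene_profile(g: OntologyGraph, corpus: AnnotationCorpus, gene: str) -> GeneProfile:
    """Build a profile from the corpus; raises DomainError if unannotated."""
    terms = frozenset(t for t in corpus.gene_terms(gene, g.namespace) if t in g)
    if not terms:
        raise DomainError(f"gene {gene!r} has no annotations in namespace {g.namespace}")
    closure: set[str] = set()
    for t in terms:
        closure |= g.ancestors(t, reflexive=True)
    return GeneProfile(gene=gene, terms=terms, closure=frozenset(closure))


def aggregate(
    sim: Callable[[str, str], float],
    p1: GeneProfile,
    p2: GeneProfile,
    mode: str = "bma",
) -> float:
    """Aggregate all-pairs term similarity between two genes' term sets.

    ``sim`` is any term-level similarity (a bound (SI, SS) combination or
    a precomputed :class:`~gosemtk.termsim.TermSimMatrix`).  ``bma`` is
    the symmetric best-match average: the mean, over each gene's terms,
    of the best similarity against the other gene's terms, averaged over
    the two directions.
    """
    if mode not in AGGREGATORS:
        raise DomainError(f"unknown aggregator {mode!r}; expected one of {AGGREGATORS}")
    t1, t2 = sorted(p1.terms), sorted(p2.terms)
    table = {(a, b): sim(a, b) for a in t1 for b in t2}
    if mode == "max":
        return max(table.values())
    if mode == "avg":
        return sum(table.values()) / len(table)
    best1 = sum(max(table[(a, b)] for b in t2) for a in t1) / len(t1)
    best2 = sum(max(table[(a, b)] for a in t1) for b in t2) / len(t2)
    return 0.5 * (best1 + best2)


# -- Jaccard family over ancestor closures ---------------------------------

def sim_ui(p1: GeneProfile, p2: GeneProfile) -> float:
    """Union-intersection similarity of ancestor closures (unweighted)."""
    inter = p1.closure & p2.closure
    union = p1.closure | p2.closure
    return len(inter) / len(union)


def _ic_mass(ic: ICTable, terms: Iterable[str]) -> float:
    return sum(ic.ic(t) for t in terms)


def sim_gic(p1: GeneProfile, p2: GeneProfile, ic: ICTable) -> float:
    """IC-weighted intersection over union of ancestor closures."""
    num = _ic_mass(ic, p1.closure & p2.closure)
    den = _ic_mass(ic, p1.closure | p2.closure)
    return num / den if den > 0 else 1.0


def sim_dic(p1: GeneProfile, p2: GeneProfile, ic: ICTable) -> float:
    """Dice-style IC overlap: 2*mass(intersection) / (mass(A)+mass(B))."""
    num = 2.0 * _ic_mass(ic, p1.closure & p2.closure)
    den = _ic_mass(ic, p1.closure) + _ic_mass(ic, p2.closure)
    return num / den if den > 0 else 1.0

def sim_uic(p1: GeneProfile, p2: GeneProfile, ic: ICTable) -> float:
    """Universal-style IC overlap: mass(intersection) / max(mass(A), mass(B))."""
    num = _ic_mass(ic, p1.closure & p2.closure)
    den = max(_ic_mass(ic, p1.closure), _ic_mass(ic, p2.closure))
    return num / den if den > 0 else 1.0


JACCARD_FUNCS = {"simui": sim_ui, "simgic": sim_gic, "simdic": sim_dic, "simuic": sim_uic}


def jaccard_similarity(name: str, p1: GeneProfile, p2: GeneProfile, ic: ICTable) -> float:
    if name not in JACCARD_FUNCS:
        raise DomainError(f"unknown Jaccard measure {name!r}; expected {JACCARD_MEASURES}")
    if name == "simui":
        return sim_ui(p1, p2)
    return JACCARD_FUNCS[name](p1, p2, ic)


# -- measure enumeration ---------------------------------------------------

@dataclass(frozen=True)
class MeasureConfig:
    """One gene-similarity measure: either (SI, SS, aggregator) x namespace
    or a Jaccard-family measure x namespace."""

    namespace: str
    si: str | None = None
    ss: str | None = None
    aggregator: str | None = None
    jaccard: str | None = None

    @property
    def name(self) -> str:
        if self.jaccard:
            return f"{self.namespace}:{self.jaccard}"
        return f"{self.namespace}:{self.si}-{self.ss}-{self.aggregator}"


def measure_scorer(
    config: "MeasureConfig",
    graph: OntologyGraph,
    ic: ICTable,
    corpus: AnnotationCorpus,
) -> Callable[[str, str], float]:
    """Bind one measure configuration into a gene-pair scoring callable.

    Profiles are built lazily and cached; unannotated genes raise
    DomainError so callers can drop and count the pair.
    """
    from .shared_info import SharedInformation
    from .termsim import term_similarity_function

    if graph.namespace != config.namespace:
        raise DomainError(
            f"measure namespace {config.namespace} != graph {graph.namespace}"
        )
    profiles: dict[str, GeneProfile] = {}

    def profile(gene: str) -> GeneProfile:
        if gene not in profiles:
            profiles[gene] = gene_profile(graph, corpus, gene)
        return profiles[gene]

    if config.jaccard:
        return lambda g1, g2: jaccard_similarity(config.jaccard, profile(g1), profile(g2), ic)
    sim = term_similarity_function(SharedInformation(graph, ic, config.si), config.ss)
    return lambda g1, g2: aggregate(sim, profile(g1), profile(g2), config.aggregator)


def enumerate_measures(
    si_names: Sequence[str] = SI_METHODS,
    ss_names: Sequence[str] = SS_METHODS,
    agg_names: Sequence[str] = ("bma",),
    include_jaccard: bool = False,
    namespaces: Sequence[str] = NAMESPACES,
) -> list[MeasureConfig]:
    """Cross product of configuration choices: |si|*|ss|*|a| per namespace,
    plus the four Jaccard measures per namespace when requested."""
    for group, vocab, label in (
        (si_names, SI_METHODS, "shared-information"),
        (ss_names, SS_METHODS, "term-similarity"),
        (agg_names, AGGREGATORS, "aggregator"),
    ):
        if not group:
            raise ValidationError(f"empty {label} vocabulary")
        unknown = set(group) - set(vocab)
        if unknown:
            raise ValidationError(f"unknown {label} names: {sorted(unknown)}")
    configs = [
        MeasureConfig(namespace=ns, si=si, ss=ss, aggregator=agg)
        for ns in namespaces
        for si, ss, agg in itertools.product(si_names, ss_names, agg_names)
    ]
    if include_jaccard:
        configs += [
            MeasureConfig(namespace=ns, jaccard=j)
            for ns in namespaces
            for j in JACCARD_MEASURES
        ]
    return configs
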