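"""Namespace-partitioned ontology DAGs parsed from OBO files.

The Gene Ontology is three disjoint rooted DAGs (biological process,
molecular function, cellular component).  Edges here are oriented
child -> parent, i.e. from a term toward more general terms, so
"ancestors of t" are exactly the nodes reachable from t.  Only ``is_a``
and ``part_of`` relationships are retained by default; the ancestor sets
used in semantic calculations are reflexive (contain the term itself).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet

from .errors import DomainError, UnknownTermError, ValidationError

logger = logging.getLogger(__name__)

#: canonical short namespace labels
NAMESPACES = ("BP", "MF", "CC")

_NS_ALIASES = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
    "BP": "BP",
    "MF": "MF",
    "CC": "CC",
    "P": "BP",
    "F": "MF",
    "C": "CC",
}

_NS_LONG = {"BP": "biological_process", "MF": "molecular_function", "CC": "cellular_component"}

DEFAULT_RELATIONS = ("is_a", "part_of")


def normalize_namespace(ns: str) -> str:
    try:
        return _NS_ALIASES[ns]
    except KeyError:
        raise ValidationError(f"unknown namespace {ns!r}; expected one of BP/MF/CC") from None


@dataclass(frozen=True)
class Term:
    """A single ontology term (concept node)."""

    id: str
    name: str = ""
    namespace: str = "BP"
    obsolete: bool = False
    alt_ids: tuple[str, ...] = ()


@dataclass
class TopologyStats:
    """Summary statistics of a namespace DAG's shape.

    ``mean_ancestors`` uses proper (non-reflexive) ancestor sets;
    ``log_n_minus_mean_anc`` compares log(n) with that mean, a gauge of
    whether the DAG behaves like a balanced tree (where ancestor counts
    grow logarithmically in the term count).
    """

    n_nodes: int
    mean_branching: float
    mean_ancestors: float
    log_n_minus_mean_anc: float


class OntologyGraph:
    """A single-namespace rooted DAG of terms with child->parent edges.

    Parameters
    ----------
    terms : iterable of Term
        Non-obsolete terms of one namespace.
    edges : iterable of (child_id, parent_id, relation)
        Directed edges toward more general terms; relation is ``is_a`` or
        ``part_of``.
    alt_id_map : mapping, optional
        Alternate accession -> canonical accession, used by :meth:`resolve`.
    obsolete_ids : set, optional
        Accessions of obsolete terms dropped at parse time; kept so that
        annotation parsing can report them.
    """

    def __init__(
        self,
        terms: Iterable[Term],
        edges: Iterable[tuple[str, str, str]],
        *,
        alt_id_map: Mapping[str, str] | None = None,
        obsolete_ids: Iterable[str] = (),
        validate: bool = True,
    ):
        self._terms: dict[str, Term] = {}
        for t in terms:
            if not t.id:
                raise ValidationError("term with empty id")
            if t.id in self._terms:
                raise ValidationError(f"duplicate term id {t.id!r}")
            self._terms[t.id] = t
        namespaces = {t.namespace for t in self._terms.values()}
        if len(namespaces) > 1:
            raise ValidationError(f"terms span multiple namespaces: {sorted(namespaces)}")
        self.namespace = normalize_namespace(next(iter(namespaces))) if namespaces else "BP"

        self._dag = nx.DiGraph()
        self._dag.add_nodes_from(self._terms)
        for child, parent, rel in edges:
            for end in (child, parent):
                if end not in self._terms:
                    raise ValidationError(f"edge endpoint {end!r} is not a loaded term")
            self._dag.add_edge(child, parent, relation=rel)

        self.alt_id_map = dict(alt_id_map or {})
        self.obsolete_ids = frozenset(obsolete_ids)
        if validate:
            self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self._dag):
            cycle = nx.find_cycle(self._dag)
            raise ValidationError(f"ontology contains a cycle through edge {cycle[0][:2]}")
        roots = [t for t in self._dag if self._dag.out_degree(t) == 0]
        if len(self._terms) and len(roots) != 1:
            raise ValidationError(
                f"{self.namespace} graph must have exactly one root, found {sorted(roots)}"
            )

    @property
    def n(self) -> int:
        return len(self._terms)

    @property
    def n_edges(self) -> int:
        return self._dag.number_of_edges()

    @property
    def root(self) -> str:
        for t in self._dag:
            if self._dag.out_degree(t) == 0:
                return t
        raise ValidationError("empty graph has no root")

    def terms(self) -> list[str]:
        return sorted(self._terms)

    def term(self, term_id: str) -> Term:
        try:
            return self._terms[term_id]
        except KeyError:
            raise UnknownTermError(term_id) from None

    def edges(self) -> set[tuple[str, str, str]]:
        return {(c, p, d["relation"]) for c, p, d in self._dag.edges(data=True)}

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._terms

    def resolve(self, accession: str) -> str | None:
        """Map an accession (possibly an alt_id) to its canonical term id.

        Returns None for obsolete or unknown accessions.
        """
        if accession in self._terms:
            return accession
        canonical = self.alt_id_map.get(accession)
        if canonical is not None and canonical in self._terms:
            return canonical
        return None

    def parents(self, term_id: str) -> set[str]:
        self.term(term_id)
        return set(self._dag.successors(term_id))

    def children(self, term_id: str) -> set[str]:
        self.term(term_id)
        return set(self._dag.predecessors(term_id))

    # -- reachability ------------------------------------------------------

    def ancestors(self, term_id: str, reflexive: bool = True) -> set[str]:
        """All terms reachable from ``term_id`` by child->parent edges."""
        self.term(term_id)
        anc = nx.descendants(self._dag, term_id)  # edges point rootward
        if reflexive:
            anc.add(term_id)
        return anc

    def descendants(self, term_id: str, reflexive: bool = True) -> set[str]:
        """All terms from which ``term_id`` is reachable (more specific terms)."""
        self.term(term_id)
        desc = nx.ancestors(self._dag, term_id)
        if reflexive:
            desc.add(term_id)
        return desc

    def common_ancestors(self, t1: str, t2: str) -> set[str]:
        """Reflexive common ancestor set; never empty (the root is shared)."""
        return self.ancestors(t1, reflexive=True) & self.ancestors(t2, reflexive=True)

    # -- statistics --------------------------------------------------------

    def topology_stats(self, log_base: float = math.e) -> TopologyStats:
        n = self.n
        if n < 1:
            raise DomainError("topology stats of an empty graph")
        mean_branching = self.n_edges / n
        mean_anc = sum(len(self.ancestors(t, reflexive=False)) for t in self._terms) / n
        return TopologyStats(
            n_nodes=n,
            mean_branching=mean_branching,
            mean_ancestors=mean_anc,
            log_n_minus_mean_anc=math.log(n, log_base) - mean_anc,
        )


def parse_obo(
    path: str | Path,
    relations: Sequence[str] = DEFAULT_RELATIONS,
) -> dict[str, OntologyGraph]:
    """Parse an OBO file into one :class:`OntologyGraph` per namespace.

    Obsolete terms are excluded from the graphs but recorded so that
    annotations pointing at them can be counted; ``alt_id`` accessions map
    to their canonical term.  Edges with relations outside ``relations``
    are dropped.  Raises :class:`ValidationError` on cycles or multiple
    roots, ``OSError`` on unreadable input.
    """
    bad = set(relations) - {"is_a", "part_of"}
    if bad:
        raise ValidationError(f"unsupported relations: {sorted(bad)}")
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read OBO file: {path}")
    multigraph = obonet.read_obo(path, ignore_obsolete=False)

    obsolete: set[str] = set()
    alt_map: dict[str, str] = {}
    by_ns: dict[str, list[Term]] = {ns: [] for ns in NAMESPACES}
    ns_of: dict[str, str] = {}
    for node, data in multigraph.nodes(data=True):
        alt_ids = tuple(data.get("alt_id", ()))
        for a in alt_ids:
            alt_map[a] = node
        if str(data.get("is_obsolete", "")).lower() == "true":
            obsolete.add(node)
            continue
        ns = normalize_namespace(data.get("namespace", "biological_process"))
        ns_of[node] = ns
        by_ns[ns].append(
            Term(id=node, name=data.get("name", ""), namespace=ns, alt_ids=alt_ids)
        )

    edges_ns: dict[str, list[tuple[str, str, str]]] = {ns: [] for ns in NAMESPACES}
    n_dropped_edges = 0
    for child, parent, rel in multigraph.edges(keys=True):
        if rel not in relations or child in obsolete or parent in obsolete:
            n_dropped_edges += 1
            continue
        if ns_of.get(child) != ns_of.get(parent):
            n_dropped_edges += 1
            continue
        edges_ns[ns_of[child]].append((child, parent, rel))
    if n_dropped_edges:
        logger.info("parse_obo: dropped %d edges (relation filter/obsolete)", n_dropped_edges)

    graphs: dict[str, OntologyGraph] = {}
    for ns in NAMESPACES:
        if not by_ns[ns]:
            continue
        graphs[ns] = OntologyGraph(
            by_ns[ns], edges_ns[ns], alt_id_map=alt_map, obsolete_ids=obsolete
        )
    return graphs


def write_obo(graphs: Mapping[str, OntologyGraph] | OntologyGraph, path: str | Path) -> None:
    """Serialize graphs back to the OBO dialect :func:`parse_obo` reads."""
    if isinstance(graphs, OntologyGraph):
        graphs = {graphs.namespace: graphs}
    lines = ["format-version: 1.2", "ontology: gosemtk-fixture", ""]
    for ns in sorted(graphs):
        g = graphs[ns]
        parent_map: dict[str, list[tuple[str, str]]] = {}
        for child, parent, rel in sorted(g.edges()):
            parent_map.setdefault(child, []).append((rel, parent))
        for tid in g.terms():
            term = g.term(tid)
            lines.append("[Term]")
            lines.append(f"id: {tid}")
            lines.append(f"name: {term.name or tid}")
            lines.append(f"namespace: {_NS_LONG[ns]}")
            for a in term.alt_ids:
                lines.append(f"alt_id: {a}")
            for rel, parent in parent_map.get(tid, []):
                if rel == "is_a":
                    lines.append(f"is_a: {parent}")
                else:
                    lines.append(f"relationship: {rel} {parent}")
            lines.append("")
    Path(path).write_text("\n".join(lines))
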