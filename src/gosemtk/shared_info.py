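"""Shared-information algorithms over common-ancestor sets.

Five interchangeable ways of summarising what two terms' common ancestors
jointly convey:

* ``casi`` -- mean IC over the full common-ancestor set (naive baseline);
* ``mica`` -- IC of the most informative common ancestor, the classic
  minimum-subsumer quantity behind Resnik similarity;
* ``grasm`` -- mean IC over the disjunctive common ancestors (DCA),
  selected by comparing directed path counts with >=;
* ``agrasm`` -- adjusted GraSM: the same selection with a strict >,
  which admits far fewer ancestors;
* ``sf`` -- semantic frontier: mean IC over common ancestors entered
  directly by an edge from either term's exclusive ancestor region, a
  linear-time stand-in for exclusively inherited common ancestors.

On tree-shaped ontologies the common ancestors form a chain and every
path count is 1 per input, so grasm degenerates to casi while agrasm and
sf both degenerate to mica.  All methods return IC(t) for t1 = t2 so the
derived Lin similarity of a term with itself is 1.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError, UnknownTermError
from .infocontent import ICTable
from .ontology import OntologyGraph

SI_METHODS = ("casi", "mica", "grasm", "agrasm", "sf")


def path_count(g: OntologyGraph, lower: str, upper: str) -> int:
    """Number of distinct directed child->parent paths from lower to upper.

    0 when ``upper`` is not an ancestor of ``lower``; 1 for the empty path
    when the two coincide.  Memoized dynamic programming over the DAG.
    """
    g.term(lower)
    g.term(upper)
    memo: dict[str, int] = {upper: 1}

    def count(node: str) -> int:
        if node in memo:
            return memo[node]
        memo[node] = total = sum(count(p) for p in g.parents(node))
        return total

    return count(lower)


@dataclass
class SharedInformation:
    """A shared-information method bound to one graph and its IC table."""

    graph: OntologyGraph
    ic: ICTable
    method: str = "mica"

    def __post_init__(self) -> None:
        if self.method not in SI_METHODS:
            raise DomainError(
                f"unknown shared-information method {self.method!r}; "
                f"expected one of {SI_METHODS}"
            )
        if self.graph.namespace != self.ic.namespace:
            raise DomainError(
                f"graph namespace {self.graph.namespace} != IC table "
                f"namespace {self.ic.namespace}"
            )

    def __call__(self, t1: str, t2: str) -> float:
        return getattr(self, f"si_{self.method}")(t1, t2)

    # -- shared plumbing ---------------------------------------------------

    def _check(self, *terms: str) -> None:
        for t in terms:
            if t not in self.graph:
                raise UnknownTermError(t)
            self.ic.ic(t)  # raises UnscoredTermError when unscored

    def _mean_ic(self, terms) -> float:
        return sum(self.ic.ic(t) for t in terms) / len(terms)

    # -- the five algorithms ----------------------------------------------

    def si_casi(self, t1: str, t2: str) -> float:
        """Mean IC over all common ancestors."""
        self._check(t1, t2)
        if t1 == t2:
            return self.ic.ic(t1)
        return self._mean_ic(self.graph.common_ancestors(t1, t2))

    def si_mica(self, t1: str, t2: str) -> float:
        """IC of the most informative common ancestor."""
        self._check(t1, t2)
        if t1 == t2:
            return self.ic.ic(t1)
        return max(self.ic.ic(t) for t in self.graph.common_ancestors(t1, t2))

    def si_grasm(self, t1: str, t2: str) -> float:
        return self._mean_ic(self.dca(t1, t2, strict=False))

    def si_agrasm(self, t1: str, t2: str) -> float:
        return self._mean_ic(self.dca(t1, t2, strict=True))

    def dca(self, t1: str, t2: str, strict: bool) -> list[str]:
        """Disjunctive common ancestors by sequential path-count comparison.

        Candidates are processed in decreasing IC order (ties broken by
        term id); the selected set is seeded with the MICA, and a
        candidate joins when its summed path count to the two inputs is
        >= (GraSM) / > (adjusted GraSM) that of every ancestor already
        selected.  The MICA is always a member and the set is a subset of
        the common ancestors.
        """
        self._check(t1, t2)
        if t1 == t2:
            return [t1]
        ca = sorted(
            self.graph.common_ancestors(t1, t2),
            key=lambda t: (-self.ic.ic(t), t),
        )
        np = {a: path_count(self.graph, t1, a) + path_count(self.graph, t2, a) for a in ca}
        selected = [ca[0]]
        for cand in ca[1:]:
            if all(np[cand] > np[s] if strict else np[cand] >= np[s] for s in selected):
                selected.append(cand)
        return selected

    def si_frontier(self, t1: str, t2: str) -> float:
        """Mean IC over the semantic frontier of the common-ancestor region."""
        return self._mean_ic(self.frontier(t1, t2))

    # spelled-out alias so method dispatch via name "sf" works
    si_sf = si_frontier

    def frontier(self, t1: str, t2: str) -> set[str]:
        """Common ancestors with an incoming edge from either input's
        exclusive ancestor region."""
        self._check(t1, t2)
        if t1 == t2:
            return {t1}
        a1 = self.graph.ancestors(t1, reflexive=True)
        a2 = self.graph.ancestors(t2, reflexive=True)
        ca = a1 & a2
        exclusive = (a1 | a2) - ca
        return {a for a in ca if self.graph.children(a) & exclusive}


# thin functional wrappers -------------------------------------------------

def si_casi(g: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    return SharedInformation(g, ic, "casi").si_casi(t1, t2)


def si_mica(g: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    return SharedInformation(g, ic, "mica").si_mica(t1, t2)


def si_grasm(g: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    return SharedInformation(g, ic, "grasm").si_grasm(t1, t2)


def si_agrasm(g: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    return SharedInformation(g, ic, "agrasm").si_agrasm(t1, t2)


def si_frontier(g: OntologyGraph, ic: ICTable, t1: str, t2: str) -> float:
    return SharedInformation(g, ic, "sf").si_frontier(t1, t2)
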