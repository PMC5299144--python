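"""GAF annotation corpora.

Reads GAF 2.x tab-separated annotation files into per-namespace corpora of
deduplicated (gene, term) records.  The occurrence-counting unit everywhere
downstream is the deduplicated pair: GAF repeats the same association
across references and evidence codes, and counting raw lines would inflate
term probabilities.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import ValidationError
from .ontology import NAMESPACES, OntologyGraph, normalize_namespace

logger = logging.getLogger(__name__)

_ASPECT_TO_NS = {"P": "BP", "F": "MF", "C": "CC"}
_NS_TO_ASPECT = {v: k for k, v in _ASPECT_TO_NS.items()}

#: experimental evidence codes, for convenience filtering
EXPERIMENTAL_CODES = frozenset({"EXP", "IDA", "IPI", "IMP", "IGI", "IEP"})


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-to-term association with its evidence code."""

    gene: str
    term: str
    evidence: str = "IEA"
    qualifier: str = ""


class AnnotationCorpus:
    """Deduplicated (gene, term) records partitioned by namespace.

    ``gene_index(ns)`` and ``term_index(ns)`` are mutually consistent
    inverses; ``dropped`` counts skipped input records by reason.
    """

    def __init__(self, dropped: Counter | None = None):
        self._records: dict[str, set[tuple[str, str]]] = {ns: set() for ns in NAMESPACES}
        self._gene_index: dict[str, dict[str, set[str]]] = {ns: {} for ns in NAMESPACES}
        self._term_index: dict[str, dict[str, set[str]]] = {ns: {} for ns in NAMESPACES}
        self.dropped: Counter = dropped if dropped is not None else Counter()

    def add(self, gene: str, term: str, namespace: str) -> None:
        ns = normalize_namespace(namespace)
        if not gene or not term:
            raise ValidationError("gene and term accessions must be non-empty")
        if (gene, term) in self._records[ns]:
            self.dropped["duplicate"] += 1
            return
        self._records[ns].add((gene, term))
        self._gene_index[ns].setdefault(gene, set()).add(term)
        self._term_index[ns].setdefault(term, set()).add(gene)

    def records(self, namespace: str) -> set[tuple[str, str]]:
        return set(self._records[normalize_namespace(namespace)])

    def n_records(self, namespace: str) -> int:
        return len(self._records[normalize_namespace(namespace)])

    def gene_index(self, namespace: str) -> dict[str, set[str]]:
        return {g: set(ts) for g, ts in self._gene_index[normalize_namespace(namespace)].items()}

    def term_index(self, namespace: str) -> dict[str, set[str]]:
        return {t: set(gs) for t, gs in self._term_index[normalize_namespace(namespace)].items()}

    def genes(self, namespace: str) -> set[str]:
        return set(self._gene_index[normalize_namespace(namespace)])

    def gene_terms(self, gene: str, namespace: str) -> set[str]:
        """Directly annotated terms of one gene; empty set if unannotated."""
        return set(self._gene_index[normalize_namespace(namespace)].get(gene, ()))

    def annotated_terms(self, namespace: str) -> set[str]:
        """Terms with at least one direct annotation in the namespace."""
        ns = normalize_namespace(namespace)
        terms = set(self._term_index[ns])
        if not terms:
            logger.warning("no annotated terms in namespace %s", ns)
        return terms


def parse_gaf(
    path: str | Path,
    graphs: Mapping[str, OntologyGraph],
    evidence_filter: Iterable[str] | str = "all",
    exclude_not: bool = True,
) -> AnnotationCorpus:
    """Parse a GAF 2.x file against loaded ontology graphs.

    Records failing the evidence filter, carrying a NOT qualifier (when
    ``exclude_not``), or pointing at unknown/obsolete terms are dropped and
    counted in ``corpus.dropped``.  Annotations to alt_id accessions are
    remapped to the canonical term.  Raises :class:`ValidationError` when
    no record survives.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read GAF file: {path}")
    if evidence_filter != "all":
        evidence_filter = frozenset(evidence_filter)

    corpus = AnnotationCorpus()
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                corpus.dropped["malformed"] += 1
                continue
            gene, qualifier, term, evidence, aspect = (
                cols[1], cols[3], cols[4], cols[6], cols[8],
            )
            if not gene or not term:
                corpus.dropped["malformed"] += 1
                continue
            if exclude_not and "NOT" in qualifier.split("|"):
                corpus.dropped["not_qualifier"] += 1
                continue
            if evidence_filter != "all" and evidence not in evidence_filter:
                corpus.dropped["evidence"] += 1
                continue
            ns = _ASPECT_TO_NS.get(aspect)
            if ns is None or ns not in graphs:
                corpus.dropped["unknown_namespace"] += 1
                continue
            g = graphs[ns]
            canonical = g.resolve(term)
            if canonical is None:
                reason = "obsolete_term" if term in g.obsolete_ids else "unknown_term"
                corpus.dropped[reason] += 1
                continue
            corpus.add(gene, canonical, ns)

    if not any(corpus.n_records(ns) for ns in NAMESPACES):
        raise ValidationError(f"no annotation records survived parsing {path}")
    if corpus.dropped:
        logger.info("parse_gaf: dropped records by reason: %s", dict(corpus.dropped))
    return corpus


def write_gaf(corpus: AnnotationCorpus, path: str | Path, db: str = "FIX") -> None:
    """Serialize a corpus back to the 15-column GAF dialect parse_gaf reads."""
    rows = ["!gaf-version: 2.1"]
    for ns in NAMESPACES:
        aspect = _NS_TO_ASPECT[ns]
        for gene, term in sorted(corpus.records(ns)):
            cols = [db, gene, gene, "", term, "GO_REF:0", "IEA", "", aspect,
                    "", "", "protein", "taxon:9606", "20160101", db]
            rows.append("\t".join(cols))
    Path(path).write_text("\n".join(rows) + "\n")
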