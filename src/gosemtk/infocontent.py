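"""Occurrence counts, term probabilities, and information content.

A term occurs whenever it or any of its descendants appears in the
annotation corpus, so the cumulative count o_t is the number of distinct
(gene, term') records with term' in the reflexive descendant set of t.
Probability is P(t) = o_t / o_root and information content
IC(t) = -log P(t).  Propagating records (not per-edge sums) keeps each
record contributing once to each ancestor, so P(root) = 1 holds exactly
even through DAG diamonds.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .annotations import AnnotationCorpus
from .errors import UnscoredTermError, ValidationError
from .ontology import OntologyGraph


def cumulative_counts(g: OntologyGraph, corpus: AnnotationCorpus) -> dict[str, int]:
    """Cumulative occurrence count o_t for every term of the graph.

    Each deduplicated (gene, term) record contributes exactly once to every
    reflexive ancestor of its term; o_root equals the total record count.
    """
    counts: Counter = Counter({t: 0 for t in g.terms()})
    for _gene, term in corpus.records(g.namespace):
        if term not in g:
            continue
        for anc in g.ancestors(term, reflexive=True):
            counts[anc] += 1
    return dict(counts)


@dataclass
class ICTable:
    """Per-term counts, probabilities and information content.

    Terms with o_t = 0 are unscored: they carry no probability or IC and
    similarity queries touching them raise :class:`UnscoredTermError`.
    """

    counts: dict[str, int]
    probabilities: dict[str, float]
    _ic: dict[str, float]
    log_base: float
    namespace: str

    @property
    def o_root(self) -> int:
        return max(self.counts.values())

    def is_scored(self, term: str) -> bool:
        return term in self._ic

    def scored_terms(self) -> set[str]:
        return set(self._ic)

    def ic(self, term: str) -> float:
        try:
            return self._ic[term]
        except KeyError:
            raise UnscoredTermError(term) from None

    def probability(self, term: str) -> float:
        try:
            return self.probabilities[term]
        except KeyError:
            raise UnscoredTermError(term) from None

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# namespace={self.namespace}\tlog_base={self.log_base!r}\n")
            fh.write("term_id\tcount\tprobability\tic\n")
            for t in sorted(self.counts):
                c = self.counts[t]
                if c > 0:
                    fh.write(f"{t}\t{c}\t{self.probabilities[t]:.10g}\t{self._ic[t]:.10g}\n")
                else:
                    fh.write(f"{t}\t0\tNA\tNA\n")


def ic_table(
    g: OntologyGraph, corpus: AnnotationCorpus, log_base: float = math.e
) -> ICTable:
    """Build the information-content table for one namespace graph.

    Raises :class:`ValidationError` if the corpus contributes no records
    (o_root = 0), in which case no probability is defined.
    """
    counts = cumulative_counts(g, corpus)
    o_root = counts.get(g.root, 0)
    if o_root <= 0:
        raise ValidationError(
            f"namespace {g.namespace}: corpus contributes no records (o_root = 0)"
        )
    probs: dict[str, float] = {}
    ic: dict[str, float] = {}
    for t, c in counts.items():
        if c > 0:
            p = c / o_root
            probs[t] = p
            ic[t] = -math.log(p, log_base)
    # -log of 1.0 can produce -0.0; normalise for clean equality checks
    ic = {t: (0.0 if v == 0 else v) for t, v in ic.items()}
    return ICTable(
        counts=counts, probabilities=probs, _ic=ic, log_base=log_base, namespace=g.namespace
    )
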