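"""Benchmark reference similarities the semantic scores are judged against.

These are the non-ontological similarity standards: relative reciprocal
BLAST score (sequence), Jaccard and TF-IDF cosine over protein domain
sets, and absolute expression-profile correlation.  The toolkit does not
run BLAST or HMMER; bit scores and domain sets arrive as pre-computed
TSV tables (upstream e-value cut-offs are table-generation parameters
and live in the table metadata, not here).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ValidationError


class MissingScoreError(DomainError):
    """A required (query, subject) score is absent; callers skip the pair."""


@dataclass
class BitScoreTable:
    """Map (query, subject) -> BLAST bit score.  Self scores must be
    present for every id used in RRBS."""

    scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def add(self, query: str, subject: str, score: float) -> None:
        if score <= 0:
            raise ValidationError(f"bit score must be positive, got {score}")
        self.scores[(query, subject)] = score

    def get(self, query: str, subject: str) -> float:
        try:
            return self.scores[(query, subject)]
        except KeyError:
            raise MissingScoreError(f"no bit score for ({query}, {subject})") from None

    @classmethod
    def read_tsv(cls, path: str | Path) -> "BitScoreTable":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["id1", "id2", "bitscore"])
        table = cls()
        for row in df.itertuples(index=False):
            table.add(str(row.id1), str(row.id2), float(row.bitscore))
        return table

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for (q, s), v in sorted(self.scores.items()):
                fh.write(f"{q}\t{s}\t{v:.6g}\n")


def rrbs(bits: BitScoreTable, a: str, b: str) -> float:
    """Relative reciprocal BLAST score:
    (bits(a,b)+bits(b,a)) / (bits(a,a)+bits(b,b)).  Exactly 1 for a
    self-pair; raises :class:`MissingScoreError` when any of the four
    scores is absent."""
    return (bits.get(a, b) + bits.get(b, a)) / (bits.get(a, a) + bits.get(b, b))


@dataclass
class DomainCorpus:
    """Proteins as multisets of functional domains.

    ``f_d`` (within-protein domain count, the term frequency) feeds the
    TF-IDF weights; the plain Jaccard measure uses the deduplicated set.
    """

    domains: dict[str, Counter] = field(default_factory=dict)

    def add(self, protein: str, domain: str, count: int = 1) -> None:
        if count < 1:
            raise ValidationError(f"domain count must be >= 1, got {count}")
        self.domains.setdefault(protein, Counter())[domain] += count

    @property
    def n_proteins(self) -> int:
        return len(self.domains)

    def domain_frequency(self) -> Counter:
        """n_d: number of proteins carrying each domain."""
        nd: Counter = Counter()
        for ds in self.domains.values():
            nd.update(set(ds))
        return nd

    def domain_set(self, protein: str) -> set[str]:
        ds = self.domains.get(protein)
        if not ds:
            raise MissingScoreError(f"protein {protein!r} has no domains")
        return set(ds)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DomainCorpus":
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["protein", "domain", "count"])
        dc = cls()
        for row in df.itertuples(index=False):
            dc.add(str(row.protein), str(row.domain), int(row.count))
        return dc

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for protein in sorted(self.domains):
                for domain, count in sorted(self.domains[protein].items()):
                    fh.write(f"{protein}\t{domain}\t{count}\n")


def domain_jaccard(dc: DomainCorpus, a: str, b: str) -> float:
    """Jaccard index of the two proteins' deduplicated domain sets."""
    da, db = dc.domain_set(a), dc.domain_set(b)
    return len(da & db) / len(da | db)


def tfidf_cosine(dc: DomainCorpus, a: str, b: str, log_base: float = math.e) -> float:
    """Cosine similarity of TF-IDF domain-weight vectors.

    Weight of domain d in a protein: w_d = f_d * log(N / n_d) with N the
    corpus protein count and n_d the number of proteins carrying d.
    Raises :class:`MissingScoreError` for a zero-norm vector (all of a
    protein's domains ubiquitous)."""
    da, db = dc.domains.get(a), dc.domains.get(b)
    if not da or not db:
        raise MissingScoreError(f"protein without domains in pair ({a}, {b})")
    nd = dc.domain_frequency()
    n = dc.n_proteins

    def weights(fd: Counter) -> dict[str, float]:
        return {d: f * math.log(n / nd[d], log_base) for d, f in fd.items()}

    wa, wb = weights(da), weights(db)
    norm_a = math.sqrt(sum(v * v for v in wa.values()))
    norm_b = math.sqrt(sum(v * v for v in wb.values()))
    if norm_a == 0 or norm_b == 0:
        raise MissingScoreError(
            f"zero-norm TF-IDF vector in pair ({a}, {b}): all domains ubiquitous"
        )
    dot = sum(wa[d] * wb[d] for d in set(wa) & set(wb))
    return dot / (norm_a * norm_b)


@dataclass
class ExpressionMatrix:
    """Gene x condition expression values (no missing entries)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.shape[1] < 2:
            raise ValidationError("expression matrix needs at least 2 conditions")
        if self.data.isna().any().any():
            raise ValidationError("expression matrix contains missing values")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t")

    def profile(self, gene: str) -> np.ndarray:
        if gene not in self.data.index:
            raise MissingScoreError(f"gene {gene!r} not in expression matrix")
        return self.data.loc[gene].to_numpy(dtype=float)


def expression_abs_corr(
    em: ExpressionMatrix, a: str, b: str, method: str = "pearson"
) -> float:
    """Absolute expression-profile correlation, detecting a relationship
    of either sign.  Constant profiles have no defined correlation and
    raise :class:`MissingScoreError` so callers can skip and count."""
    xa, xb = em.profile(a), em.profile(b)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        raise MissingScoreError(f"constant expression profile in pair ({a}, {b})")
    if method == "pearson":
        r = stats.pearsonr(xa, xb).statistic
    elif method == "spearman":
        r = stats.spearmanr(xa, xb).statistic
    else:
        raise DomainError(f"unknown correlation method {method!r}")
    return abs(float(r))
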