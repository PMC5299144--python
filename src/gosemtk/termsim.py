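"""Term-level semantic similarity and precomputed similarity matrices.

Any shared-information (SI) method substitutes into three classical
information-theoretic term similarities:

    Resnik(t1,t2) = SI(t1,t2)
    Lin(t1,t2)    = 2*SI(t1,t2) / (IC(t1)+IC(t2))
    JC(t1,t2)     = 1 - (IC(t1)+IC(t2) - 2*SI(t1,t2))

Jiang-Conrath is kept exactly in this affine form: it may be negative or
exceed 1, and no clamping is applied; consumers needing [0,1] rescale
explicitly.  Matrices are restricted to corpus-annotated terms and store
the upper triangle plus diagonal, exploiting sim(a,b) = sim(b,a).
"""

from __future__ import annotations

import gzip
import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .annotations import AnnotationCorpus
from .errors import DomainError, ValidationError
from .infocontent import ICTable
from .ontology import OntologyGraph
from .shared_info import SI_METHODS, SharedInformation

SS_METHODS = ("resnik", "lin", "jc")


def ss_resnik(si: SharedInformation, t1: str, t2: str) -> float:
    """Resnik similarity: the shared information itself."""
    return si(t1, t2)


def ss_lin(si: SharedInformation, t1: str, t2: str) -> float:
    """Lin similarity; 1 at identity (0/0 limit at the root defined as 1)."""
    if t1 == t2:
        si.ic.ic(t1)
        return 1.0
    denom = si.ic.ic(t1) + si.ic.ic(t2)
    if denom == 0.0:
        # both terms carry zero information; they are indistinguishable
        return 1.0
    return 2.0 * si(t1, t2) / denom


def ss_jc(si: SharedInformation, t1: str, t2: str) -> float:
    """Jiang-Conrath similarity, un-normalized affine form."""
    return 1.0 - (si.ic.ic(t1) + si.ic.ic(t2) - 2.0 * si(t1, t2))


_SS_FUNCS = {"resnik": ss_resnik, "lin": ss_lin, "jc": ss_jc}


def term_similarity_function(si: SharedInformation, ss_name: str):
    """Bind an SS formula over an SI method into a callable f(t1, t2)."""
    if ss_name not in SS_METHODS:
        raise DomainError(f"unknown term similarity {ss_name!r}; expected {SS_METHODS}")
    func = _SS_FUNCS[ss_name]
    return lambda t1, t2: func(si, t1, t2)


def count_pairs(n: int) -> int:
    """Elements in the strict upper triangle of an n x n matrix: n(n-1)/2."""
    if n < 0:
        raise DomainError(f"negative term count: {n}")
    return n * (n - 1) // 2


@dataclass
class TermSimMatrix:
    """Upper-triangular term-similarity matrix over annotated terms.

    ``terms`` is the sorted accession list; ``values`` holds the strict
    upper triangle row-major (n(n-1)/2 entries) and ``diagonal`` the n
    self-similarities.  ``metadata`` records the SI method, term
    similarity, log base, namespace and a corpus hash so a matrix is never
    silently combined with the wrong ontology or corpus.
    """

    terms: list[str]
    values: np.ndarray
    diagonal: np.ndarray
    metadata: dict[str, str]
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        n = len(self.terms)
        if len(self.values) != count_pairs(n) or len(self.diagonal) != n:
            raise ValidationError(
                f"matrix size mismatch: {n} terms but {len(self.values)} "
                f"off-diagonal and {len(self.diagonal)} diagonal entries"
            )
        self._index = {t: i for i, t in enumerate(self.terms)}

    @property
    def n(self) -> int:
        return len(self.terms)

    def _flat(self, i: int, j: int) -> int:
        # row-major strict upper triangle, i < j
        return i * (2 * self.n - i - 1) // 2 + (j - i - 1)

    def sim(self, t1: str, t2: str) -> float:
        try:
            i, j = self._index[t1], self._index[t2]
        except KeyError as e:
            raise DomainError(f"term {e.args[0]!r} not in similarity matrix") from None
        if i == j:
            return float(self.diagonal[i])
        if i > j:
            i, j = j, i
        return float(self.values[self._flat(i, j)])

    __call__ = sim


def corpus_hash(corpus: AnnotationCorpus, namespace: str) -> str:
    payload = "\n".join(f"{g}\t{t}" for g, t in sorted(corpus.records(namespace)))
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def build_matrix(
    g: OntologyGraph,
    ic: ICTable,
    si_name: str,
    ss_name: str,
    corpus: AnnotationCorpus,
) -> TermSimMatrix:
    """Precompute similarities for all pairs of corpus-annotated terms.

    Only the n(n-1)/2 upper-triangle pairs plus the n diagonal entries are
    evaluated.  Raises :class:`ValidationError` when the corpus annotates
    no term of the graph's namespace.
    """
    terms = sorted(t for t in corpus.annotated_terms(g.namespace) if t in g)
    if not terms:
        raise ValidationError(f"no annotated terms in namespace {g.namespace}")
    si = SharedInformation(g, ic, si_name)
    f = term_similarity_function(si, ss_name)
    n = len(terms)
    values = np.empty(count_pairs(n))
    diagonal = np.empty(n)
    k = 0
    for i in range(n):
        diagonal[i] = f(terms[i], terms[i])
        for j in range(i + 1, n):
            values[k] = f(terms[i], terms[j])
            k += 1
    metadata = {
        "si": si_name,
        "ss": ss_name,
        "log_base": repr(ic.log_base),
        "namespace": g.namespace,
        "corpus_hash": corpus_hash(corpus, g.namespace),
    }
    return TermSimMatrix(terms=terms, values=values, diagonal=diagonal, metadata=metadata)


def _open_text(path: str | Path, mode: str):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_matrix(matrix: TermSimMatrix, path: str | Path) -> None:
    """Write the long-form TSV dialect ('.gz' suffix gzips): '#'-prefixed
    metadata header, then one `term1 term2 value` row per stored entry
    (diagonal included)."""
    with _open_text(path, "w") as fh:
        for key in sorted(matrix.metadata):
            fh.write(f"# {key}={matrix.metadata[key]}\n")
        fh.write(f"# n_terms={matrix.n}\n")
        for i, t in enumerate(matrix.terms):
            fh.write(f"{t}\t{t}\t{matrix.diagonal[i]:.12g}\n")
        for i in range(matrix.n):
            for j in range(i + 1, matrix.n):
                v = matrix.values[matrix._flat(i, j)]
                fh.write(f"{matrix.terms[i]}\t{matrix.terms[j]}\t{v:.12g}\n")


def read_matrix(
    path: str | Path,
    g: OntologyGraph | None = None,
    corpus: AnnotationCorpus | None = None,
) -> TermSimMatrix:
    """Reload a matrix; validates metadata against an ontology/corpus when
    given and rejects truncated files or terms missing from the ontology."""
    metadata: dict[str, str] = {}
    entries: dict[tuple[str, str], float] = {}
    terms: set[str] = set()
    with _open_text(path, "r") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                metadata[key.strip()] = value
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValidationError(f"malformed matrix row: {line!r}")
            t1, t2, v = parts
            entries[(t1, t2) if t1 <= t2 else (t2, t1)] = float(v)
            terms.update((t1, t2))

    n_declared = metadata.pop("n_terms", None)
    term_list = sorted(terms)
    n = len(term_list)
    if n_declared is not None and int(n_declared) != n:
        raise ValidationError(
            f"matrix file truncated: header declares {n_declared} terms, found {n}"
        )
    if len(entries) != count_pairs(n) + n:
        raise ValidationError(
            f"matrix file truncated: expected {count_pairs(n) + n} entries, "
            f"found {len(entries)}"
        )
    if g is not None:
        missing = [t for t in term_list if t not in g]
        if missing:
            raise ValidationError(f"matrix terms not in ontology: {missing[:5]}")
        if metadata.get("namespace") not in (None, g.namespace):
            raise ValidationError(
                f"matrix namespace {metadata.get('namespace')} != graph {g.namespace}"
            )
    if corpus is not None and "corpus_hash" in metadata and g is not None:
        if metadata["corpus_hash"] != corpus_hash(corpus, g.namespace):
            raise ValidationError("matrix corpus hash does not match the given corpus")

    values = np.empty(count_pairs(n))
    diagonal = np.empty(n)
    index = {t: i for i, t in enumerate(term_list)}
    for (t1, t2), v in entries.items():
        i, j = index[t1], index[t2]
        if i == j:
            diagonal[i] = v
        else:
            values[i * (2 * n - i - 1) // 2 + (j - i - 1)] = v
    return TermSimMatrix(terms=term_list, values=values, diagonal=diagonal, metadata=metadata)
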