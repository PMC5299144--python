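"""Statistical benchmarking harness.

Every benchmark reduces a gene-pair score table to a per-measure
*performance distribution* — one statistic value per bootstrap or
cross-validation replicate — which then feeds tie-aware ranking,
factor-influence regression, and ensemble evaluation:

* Spearman rank correlation against a reference similarity;
* ROC/AUC for labeled interaction pairs;
* Ward clustering scored by variation-of-information similarity against
  a known partition;
* F-score-maximising threshold classifiers combined by majority voting
  and judged by k-fold cross-validation error.

All resampling is driven by an explicit seed schedule (base seed +
replicate index), so distributions are exactly reproducible.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import roc_auc_score

from .errors import DomainError, ValidationError

logger = logging.getLogger(__name__)


# -- score tables ----------------------------------------------------------

@dataclass
class PairScoreTable:
    """Rows of (id1, id2) pairs with reference/label and measure columns.

    Unordered pairs must be unique; a ``label`` column, when present,
    holds binary interaction classes.
    """

    data: pd.DataFrame
    dropped: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("id1", "id2"):
            if col not in self.data.columns:
                raise ValidationError(f"pair table must have an {col!r} column")
        keys = [tuple(sorted(p)) for p in zip(self.data["id1"], self.data["id2"])]
        if len(set(keys)) != len(keys):
            raise ValidationError("pair table contains duplicate unordered pairs")
        if "label" in self.data.columns:
            bad = set(self.data["label"].unique()) - {0, 1}
            if bad:
                raise ValidationError(f"labels must be 0/1, found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def measures(self) -> list[str]:
        reserved = {"id1", "id2", "label", "reference"}
        return [c for c in self.data.columns if c not in reserved]


# -- elementary statistics -------------------------------------------------

def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rho: Pearson correlation of average-tie ranks."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DomainError("spearman needs two equal-length sequences of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("spearman undefined for constant input")
    return float(stats.spearmanr(x, y).statistic)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve; tie handling makes it equal the
    Mann-Whitney pair-comparison statistic divided by n_pos * n_neg."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise DomainError("roc_auc requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# -- performance distributions ---------------------------------------------

@dataclass
class PerformanceDistribution:
    """Replicate statistic values for one measure on one benchmark."""

    measure: str
    statistic: str
    replicates: np.ndarray
    n_redrawn: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if len(self.replicates) > 1 else 0.0

    @property
    def B(self) -> int:
        return len(self.replicates)


def bootstrap_distribution(
    table: PairScoreTable,
    measure: str,
    statistic: str,
    B: int,
    m: int,
    seed: int,
    reference: str = "reference",
    max_redraws_per_replicate: int = 100,
) -> PerformanceDistribution:
    """Bootstrap a performance statistic for one measure column.

    Draws B with-replacement samples of size m (m may exceed the table
    size) and evaluates the statistic on each; replicate r uses RNG seed
    ``seed + r``.  ``statistic`` is ``spearman_rho`` (against the
    ``reference`` column) or ``auc`` (against the ``label`` column).
    Degenerate samples (constant columns, single-class) are redrawn and
    counted.
    """
    if len(table) < 2:
        raise DomainError("bootstrap needs at least 2 rows")
    if statistic == "spearman_rho":
        cols = [measure, reference]
        func = lambda df: spearman(df[measure], df[reference])
    elif statistic == "auc":
        cols = [measure, "label"]
        func = lambda df: roc_auc(df[measure], df["label"])
    else:
        raise DomainError(f"unknown bootstrap statistic {statistic!r}")
    for c in cols:
        if c not in table.data.columns:
            raise DomainError(f"table lacks required column {c!r}")

    frame = table.data[cols].reset_index(drop=True)
    values = np.empty(B)
    n_redrawn = 0
    for r in range(B):
        rng = np.random.default_rng(seed + r)
        for attempt in range(max_redraws_per_replicate + 1):
            idx = rng.integers(0, len(frame), size=m)
            try:
                values[r] = func(frame.iloc[idx])
                break
            except DomainError:
                n_redrawn += 1
        else:
            raise DomainError(
                f"replicate {r} degenerate after {max_redraws_per_replicate} redraws"
            )
    if n_redrawn:
        logger.info("bootstrap_distribution(%s): %d samples redrawn", measure, n_redrawn)
    return PerformanceDistribution(
        measure=measure, statistic=statistic, replicates=values, n_redrawn=n_redrawn
    )


# -- partitions and variation of information -------------------------------

@dataclass
class Partition:
    """Assignment of items to clusters."""

    labels: dict[str, int]

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    def items(self) -> set[str]:
        return set(self.labels)


def _entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def vi_distance(p: Partition, q: Partition, normalized: bool = False) -> float:
    """Variation of information VI = H(P) + H(Q) - 2 I(P;Q), in nats.

    A metric on partitions; ``normalized`` divides by log(item count) so
    the value lies in [0, 1] and 1 - normalized VI is a similarity.
    """
    if p.items() != q.items():
        raise DomainError("partitions must cover the same item set")
    items = sorted(p.items())
    if len(items) < 2:
        raise DomainError("variation of information needs >= 2 items")
    a = np.array([p.labels[i] for i in items])
    b = np.array([q.labels[i] for i in items])
    contingency = pd.crosstab(a, b).to_numpy().astype(float)
    h_p = _entropy(contingency.sum(axis=1))
    h_q = _entropy(contingency.sum(axis=0))
    h_pq = _entropy(contingency.ravel())
    mi = h_p + h_q - h_pq
    vi = max(h_p + h_q - 2.0 * mi, 0.0)
    if normalized:
        vi /= math.log(len(items))
    return vi


def vi_similarity(p: Partition, q: Partition) -> float:
    """1 - normalized VI distance; 1 for identical partitions."""
    return 1.0 - vi_distance(p, q, normalized=True)


def cluster_and_score(
    distances: pd.DataFrame, true_partition: Partition, k: int
) -> float:
    """Ward-linkage hierarchical clustering cut at k clusters, scored by
    VI similarity against a known partition.

    ``distances`` is a complete square symmetric matrix indexed by item;
    the Ward update follows the squared-distance (Ward.D2-style)
    Lance-Williams recursion of scipy.
    """
    items = list(distances.index)
    if set(items) != true_partition.items():
        raise DomainError("distance matrix items do not match the true partition")
    if k > len(items):
        raise DomainError(f"cannot cut {len(items)} items into {k} clusters")
    square = distances.loc[items, items].to_numpy(dtype=float)
    if np.isnan(square).any():
        raise DomainError("distance matrix is incomplete (contains NaN)")
    condensed = squareform(square, checks=True)
    Z = linkage(condensed, method="ward")
    # the Ward recursion on non-Euclidean dissimilarities can emit slightly
    # negative or non-monotone merge heights; only the merge order matters
    # for a maxclust cut, so monotonize the heights
    Z[:, 2] = np.maximum.accumulate(np.maximum(Z[:, 2], 0.0))
    flat = fcluster(Z, t=k, criterion="maxclust")
    pred = Partition({item: int(c) for item, c in zip(items, flat)})
    return vi_similarity(pred, true_partition)


# -- tie-aware ranking and factor regression -------------------------------

def welch_tied(a: PerformanceDistribution, b: PerformanceDistribution,
               alpha: float = 0.05) -> bool:
    """True when Welch's t-test cannot reject equal means at level alpha."""
    if a.sd == 0 and b.sd == 0:
        logger.info("welch_tied: zero-variance pair, exact mean comparison")
        return a.mean == b.mean
    p = stats.ttest_ind(a.replicates, b.replicates, equal_var=False).pvalue
    return bool(p > alpha)


def rank_with_ties(
    dists: Sequence[PerformanceDistribution],
    higher_is_better: bool = True,
    alpha: float = 0.05,
) -> dict[str, int]:
    """Competition ("exhausted") ranking with statistical ties.

    Methods are sorted by mean performance; a method joins the current
    tie chain when Welch's test against the chain leader fails to reject
    equal means.  Tied methods share the chain's best rank and the next
    chain starts past the tie block (1, 1, 3, ...).
    """
    if len(dists) < 2:
        raise DomainError("ranking needs at least 2 distributions")
    order = sorted(dists, key=lambda d: -d.mean if higher_is_better else d.mean)
    ranks: dict[str, int] = {}
    i = 0
    while i < len(order):
        chain = [order[i]]
        j = i + 1
        while j < len(order) and welch_tied(order[i], order[j], alpha):
            chain.append(order[j])
            j += 1
        for d in chain:
            ranks[d.measure] = i + 1
        i = j
    return ranks


def factor_influence(
    table: pd.DataFrame, response: str = "response"
) -> dict[str, dict[str, float]]:
    """Sequential ANOVA of mean performance on categorical design factors.

    ``table`` has one row per measure configuration with categorical
    factor columns (e.g. ontology, term similarity, shared information)
    and a numeric response.  Returns per factor the ANOVA p-value and
    -log10(p), the influence scale used in reporting.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    factors = [c for c in table.columns if c != response]
    if not factors:
        raise ValidationError("factor table has no factor columns")
    for f in factors:
        if table[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has fewer than 2 levels")
    for f1, f2 in itertools.combinations(factors, 2):
        if (table[f1].astype(str) == table[f2].astype(str)).all():
            raise ValidationError(f"factors {f1!r} and {f2!r} are aliased (identical)")
    n_dummies = sum(table[f].nunique() - 1 for f in factors) + 1
    if len(table) <= n_dummies:
        raise ValidationError(
            f"{len(table)} rows cannot identify {n_dummies} design columns"
        )
    formula = f"{response} ~ " + " + ".join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=table).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    out: dict[str, dict[str, float]] = {}
    for f in factors:
        p = float(anova.loc[f"C({f})", "PR(>F)"])
        out[f] = {"p": p, "neg_log10_p": -math.log10(p) if p > 0 else math.inf}
    return out


# -- threshold classifiers, voting, cross-validation -----------------------

@dataclass
class ThresholdClassifier:
    """Predict positive when the measure's score is >= threshold."""

    measure: str
    threshold: float
    f_score: float

    def predict(self, scores: Sequence[float]) -> np.ndarray:
        return (np.asarray(scores, dtype=float) >= self.threshold).astype(int)


def f_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def train_threshold(
    scores: Sequence[float], labels: Sequence[int], measure: str = "score"
) -> ThresholdClassifier:
    """Pick the observed score value maximising the F-score as threshold.

    All unique score values are scanned as candidate thresholds (predict
    positive at score >= threshold); F-score ties resolve to the smallest
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(set(labels.tolist())) < 2:
        raise DomainError("threshold training requires both classes present")
    n_pos = int(labels.sum())
    best_t, best_f = None, -1.0
    for t in np.unique(scores):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        precision = tp / (tp + fp) if (tp + fp) else 0.0
        recall = tp / n_pos
        f = f_score(precision, recall)
        if f > best_f:
            best_t, best_f = float(t), f
    return ThresholdClassifier(measure=measure, threshold=best_t, f_score=best_f)


def majority_vote(
    classifiers: Sequence[ThresholdClassifier],
    pair_scores: Mapping[str, Sequence[float]],
) -> np.ndarray:
    """Positive only when strictly more than half the panel votes positive
    (an even split is a negative prediction)."""
    if not classifiers:
        raise DomainError("majority vote needs at least one classifier")
    votes = []
    for clf in classifiers:
        if clf.measure not in pair_scores:
            raise DomainError(f"no scores for panel member {clf.measure!r}")
        votes.append(clf.predict(pair_scores[clf.measure]))
    votes = np.vstack(votes)
    return (votes.sum(axis=0) > len(classifiers) / 2).astype(int)


def _fold_assignment(n: int, k: int, seed: int) -> np.ndarray:
    perm = np.random.default_rng(seed).permutation(n)
    folds = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, k)):
        folds[chunk] = f
    return folds


def kfold_cv(
    table: PairScoreTable,
    measures: Sequence[str],
    k: int = 10,
    seed: int = 0,
    panels: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, PerformanceDistribution]:
    """k-fold cross-validation of threshold classifiers and voting panels.

    Rows are randomly (seeded, unstratified) split into k folds; per
    fold, thresholds are trained on the other k-1 folds and the held-out
    misclassification rate recorded.  ``panels`` maps ensemble names to
    member measure lists evaluated by majority vote with the same
    per-fold classifiers.  Returns a ``cv_error`` distribution per
    measure and per panel.  If any training split lacks a class the
    folds are reshuffled once with an incremented seed, then the run
    fails.
    """
    if k < 2:
        raise DomainError("cross-validation needs k >= 2")
    if "label" not in table.data.columns:
        raise DomainError("cross-validation needs a label column")
    panels = dict(panels or {})
    for name, members in panels.items():
        missing = set(members) - set(measures)
        if missing:
            raise DomainError(f"panel {name!r} references untrained measures {missing}")
    df = table.data.reset_index(drop=True)
    labels = df["label"].to_numpy(dtype=int)

    folds = None
    for attempt_seed in (seed, seed + 1):
        candidate = _fold_assignment(len(df), k, attempt_seed)
        ok = all(len(set(labels[candidate != f].tolist())) == 2 for f in range(k))
        if ok:
            folds = candidate
            if attempt_seed != seed:
                logger.warning("kfold_cv: reshuffled folds with seed %d", attempt_seed)
            break
    if folds is None:
        raise ValidationError("a training split lacks one class even after reshuffling")

    errors: dict[str, list[float]] = {m: [] for m in measures}
    for name in panels:
        errors[name] = []
    for f in range(k):
        train, test = df[folds != f], df[folds == f]
        y_test = test["label"].to_numpy(dtype=int)
        clfs = {
            m: train_threshold(train[m], train["label"], measure=m) for m in measures
        }
        for m in measures:
            pred = clfs[m].predict(test[m])
            errors[m].append(float((pred != y_test).mean()))
        for name, members in panels.items():
            pred = majority_vote(
                [clfs[m] for m in members], {m: test[m] for m in members}
            )
            errors[name].append(float((pred != y_test).mean()))
    return {
        name: PerformanceDistribution(
            measure=name, statistic="cv_error", replicates=np.array(errs)
        )
        for name, errs in errors.items()
    }
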