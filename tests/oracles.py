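"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (set closures, exhaustive path
enumeration, pairwise counting) and shares no code with the package
beyond reading graph edges.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations


def closure_ancestors(edges: set[tuple[str, str]], node: str) -> set[str]:
    """Reflexive ancestor set by iterated edge expansion (transitive closure)."""
    anc = {node}
    changed = True
    while changed:
        changed = False
        for child, parent in edges:
            if child in anc and parent not in anc:
                anc.add(parent)
                changed = True
    return anc


def enumerate_paths(edges: set[tuple[str, str]], lower: str, upper: str) -> int:
    """Count child->parent paths by exhaustive depth-first enumeration."""
    if lower == upper:
        return 1
    total = 0
    for child, parent in edges:
        if child == lower:
            total += enumerate_paths(edges, parent, upper)
    return total


def mean_ic(ic: dict[str, float], terms) -> float:
    terms = list(terms)
    return sum(ic[t] for t in terms) / len(terms)


def ic_from_records(edges, all_nodes, records, base=2.0) -> dict[str, float]:
    """IC table from first principles: per-term descendant-record counting."""
    counts = {}
    for t in all_nodes:
        desc = {n for n in all_nodes if t in closure_ancestors(edges, n)}
        counts[t] = sum(1 for _g, term in records if term in desc)
    o_root = max(counts.values())
    return {
        t: -math.log(c / o_root, base) for t, c in counts.items() if c > 0
    }


def auc_by_pair_counting(scores, labels) -> float:
    """Mann-Whitney AUC: fraction of (pos, neg) pairs ranked correctly,
    ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def vi_by_entropy(assign_p: dict, assign_q: dict) -> float:
    """Variation of information from raw entropy arithmetic (nats)."""
    items = sorted(assign_p)
    n = len(items)

    def entropy(assign):
        counts = Counter(assign[i] for i in items)
        return -sum(c / n * math.log(c / n) for c in counts.values())

    joint = Counter((assign_p[i], assign_q[i]) for i in items)
    h_joint = -sum(c / n * math.log(c / n) for c in joint.values())
    h_p, h_q = entropy(assign_p), entropy(assign_q)
    mi = h_p + h_q - h_joint
    return h_p + h_q - 2 * mi


def spearman_by_ranks(x, y) -> float:
    """Spearman's rho from average ranks and the Pearson formula."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / math.sqrt(vx * vy)


def best_f_by_exhaustive_scan(scores, labels):
    """(threshold, F) maximising F over all unique candidate thresholds."""
    best = (None, -1.0)
    n_pos = sum(labels)
    for t in sorted(set(scores)):
        tp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 1)
        fp = sum(1 for s, l in zip(scores, labels) if s >= t and l == 0)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / n_pos
        f = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        if f > best[1]:
            best = (t, f)
    return best
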