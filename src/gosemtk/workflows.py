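"""End-to-end benchmark workflows on the planted synthetic scenarios.

Each function regenerates its scenario from a seed, runs the full
pipeline (annotation -> IC -> semantic measure -> statistical harness)
and returns plain numbers, so the same code backs the test suite, the
reproduction script and the README example.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import (
    PairScoreTable,
    bootstrap_distribution,
    cluster_and_score,
    kfold_cv,
    roc_auc,
    spearman,
)
from .fixtures import synthetic_benchmark_tables
from .genesim import MeasureConfig, measure_scorer
from .infocontent import ic_table
from .reference import rrbs


def planted_ppi_benchmark(seed: int, B: int = 100) -> dict[str, float]:
    """Protein-interaction prediction on the planted-module scenario.

    Scores every labeled pair with the best-match-average Lin/MICA
    measure computed from the scenario's own ontology and corpus, and
    reports: the full-data AUC, the Spearman correlation between the
    semantic score and the RRBS sequence reference, and the mean/sd of a
    B-replicate bootstrap AUC distribution under label permutation (the
    chance baseline).
    """
    tables = synthetic_benchmark_tables("ppi_signal", seed=seed)
    g = tables.graphs["BP"]
    ic = ic_table(g, tables.corpus)
    scorer = measure_scorer(
        MeasureConfig(namespace="BP", si="mica", ss="lin", aggregator="bma"),
        g, ic, tables.corpus,
    )
    df = tables.pairs.data.copy()
    df["BP:mica-lin-bma"] = [scorer(a, b) for a, b in zip(df["id1"], df["id2"])]
    df["reference"] = [rrbs(tables.bitscores, a, b) for a, b in zip(df["id1"], df["id2"])]

    auc = roc_auc(df["BP:mica-lin-bma"], df["label"])
    rho = spearman(df["BP:mica-lin-bma"], df["reference"])

    rng = np.random.default_rng(seed + 1)
    permuted = df.copy()
    permuted["label"] = rng.permutation(permuted["label"].to_numpy())
    dist = bootstrap_distribution(
        PairScoreTable(permuted), "BP:mica-lin-bma", "auc",
        B=B, m=len(permuted), seed=seed + 2,
    )
    return {
        "auc": auc,
        "rrbs_spearman": rho,
        "permuted_auc_mean": dist.mean,
        "permuted_auc_sd": dist.sd,
    }


def planted_pathway_recovery(seed: int, k: int | None = None) -> float:
    """Ward-cluster the planted-pathway genes on 1 - SimGIC distances and
    return the variation-of-information similarity to the true pathways."""
    tables = synthetic_benchmark_tables("pathways", seed=seed)
    g = tables.graphs["BP"]
    ic = ic_table(g, tables.corpus)
    scorer = measure_scorer(MeasureConfig(namespace="BP", jaccard="simgic"),
                            g, ic, tables.corpus)
    genes = sorted(tables.pathways.labels)
    dist = pd.DataFrame(0.0, index=genes, columns=genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            d = 1.0 - scorer(a, b)
            dist.loc[a, b] = dist.loc[b, a] = d
    return cluster_and_score(dist, tables.pathways, k=k or tables.pathways.k)


def multiview_ensemble_cv(seed: int, folds: int = 10) -> dict[str, float]:
    """Cross-validation errors of single measures and voting panels on the
    multiview scenario (independent per-namespace signal).

    Returns mean CV error for the best single measure, the all-measure
    voting panel, and per-namespace panels alongside their best member.
    """
    tables = synthetic_benchmark_tables("multiview", seed=seed)
    table = tables.pairs
    measures = table.measures
    by_ns: dict[str, list[str]] = {}
    for m in measures:
        by_ns.setdefault(m.split(":")[0], []).append(m)
    panels = {f"vote_{ns}": members for ns, members in by_ns.items()}
    panels["vote_all"] = list(measures)
    results = kfold_cv(table, measures, k=folds, seed=seed, panels=panels)

    out: dict[str, float] = {
        "best_single_error": min(results[m].mean for m in measures),
        "vote_all_error": results["vote_all"].mean,
    }
    for ns, members in by_ns.items():
        out[f"vote_{ns}_error"] = results[f"vote_{ns}"].mean
        out[f"best_{ns}_error"] = min(results[m].mean for m in members)
    return out
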