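import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gosemtk import (
    DomainError,
    PairScoreTable,
    Partition,
    PerformanceDistribution,
    ValidationError,
    bootstrap_distribution,
    cluster_and_score,
    factor_influence,
    kfold_cv,
    majority_vote,
    rank_with_ties,
    roc_auc,
    spearman,
    train_threshold,
    vi_distance,
    vi_similarity,
)
from gosemtk.evaluation import ThresholdClassifier

from .oracles import (
    auc_by_pair_counting,
    best_f_by_exhaustive_scan,
    spearman_by_ranks,
    vi_by_entropy,
)


class TestSpearman:
    def test_examples(self):
        assert spearman([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]) == pytest.approx(-1.0)
        assert spearman([1, 2, 3], [3, 1, 2]) == pytest.approx(-0.5)

    def test_constant_input_rejected(self):
        with pytest.raises(DomainError):
            spearman([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_rank_arithmetic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=12).astype(float)  # ties likely
        y = rng.normal(size=12)
        if np.ptp(x) == 0:
            return
        assert spearman(x, y) == pytest.approx(spearman_by_ranks(x, y))


class TestRocAuc:
    def test_examples(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0]) == 0.5
        assert roc_auc([0.9, 0.4, 0.8, 0.3], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(50))
    def test_equals_mann_whitney_count(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 20))
        scores = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            return
        assert roc_auc(scores, labels) == pytest.approx(
            auc_by_pair_counting(scores, labels))


class TestBootstrap:
    def _table(self, n=50, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        return PairScoreTable(pd.DataFrame({
            "id1": [f"a{i}" for i in range(n)],
            "id2": [f"b{i}" for i in range(n)],
            "m": x,
            "reference": x,  # perfectly monotone
        }))

    def test_perfect_correlation_has_zero_spread(self):
        dist = bootstrap_distribution(self._table(), "m", "spearman_rho",
                                      B=20, m=30, seed=5)
        assert np.allclose(dist.replicates, 1.0)
        assert dist.sd == pytest.approx(0.0, abs=1e-12)

    def test_fixed_seed_is_deterministic(self):
        a = bootstrap_distribution(self._table(), "m", "spearman_rho", B=10, m=25, seed=3)
        b = bootstrap_distribution(self._table(), "m", "spearman_rho", B=10, m=25, seed=3)
        assert np.array_equal(a.replicates, b.replicates)

    def test_mean_consistent_with_full_data_statistic(self):
        rng = np.random.default_rng(11)
        n = 400
        x = np.arange(n, dtype=float)
        y = x + rng.normal(scale=60.0, size=n)
        table = PairScoreTable(pd.DataFrame({
            "id1": [f"a{i}" for i in range(n)],
            "id2": [f"b{i}" for i in range(n)],
            "m": x, "reference": y,
        }))
        dist = bootstrap_distribution(table, "m", "spearman_rho", B=200, m=n, seed=7)
        full = spearman(x, y)
        se = dist.sd / np.sqrt(dist.B)
        assert abs(dist.mean - full) <= max(3 * se, 3 * dist.sd / np.sqrt(n) + 0.02)

    def test_degenerate_samples_redrawn_and_counted(self):
        # one dominant constant value makes constant samples likely at m=3
        df = pd.DataFrame({
            "id1": [f"a{i}" for i in range(6)],
            "id2": [f"b{i}" for i in range(6)],
            "m": [1.0, 1.0, 1.0, 1.0, 1.0, 2.0],
            "reference": [1.0, 1.0, 1.0, 1.0, 1.0, 2.0],
        })
        dist = bootstrap_distribution(PairScoreTable(df), "m", "spearman_rho",
                                      B=30, m=3, seed=0)
        assert dist.n_redrawn > 0
        assert dist.B == 30


class TestVariationOfInformation:
    def test_identical_partitions(self):
        p = Partition({"a": 0, "b": 0, "c": 1, "d": 1})
        assert vi_distance(p, p) == 0.0
        assert vi_similarity(p, p) == 1.0

    def test_maximally_crossed_quartet(self):
        p = Partition({"1": 0, "2": 0, "3": 1, "4": 1})
        q = Partition({"1": 0, "3": 0, "2": 1, "4": 1})
        assert vi_distance(p, q, normalized=True) == pytest.approx(1.0)
        assert vi_similarity(p, q) == pytest.approx(0.0)

    def test_mismatched_items_rejected(self):
        p = Partition({"a": 0, "b": 1})
        q = Partition({"a": 0, "c": 1})
        with pytest.raises(DomainError):
            vi_distance(p, q)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(2, 12), st.data())
    def test_metric_axioms(self, n, data):
        """Non-negativity, identity of indiscernibles (up to relabel),
        symmetry, triangle inequality on random partition triples."""
        items = [f"i{j}" for j in range(n)]
        parts = []
        for _ in range(3):
            labels = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
            parts.append(Partition(dict(zip(items, labels))))
        p, q, r = parts
        oracle = vi_by_entropy(p.labels, q.labels)
        assert vi_distance(p, q) == pytest.approx(oracle, abs=1e-10)
        assert vi_distance(p, q) >= 0.0
        assert vi_distance(p, q) == pytest.approx(vi_distance(q, p))
        assert vi_distance(p, r) <= vi_distance(p, q) + vi_distance(q, r) + 1e-9


class TestClustering:
    def _blob_distances(self, groups):
        items = sorted(groups)
        d = pd.DataFrame(0.0, index=items, columns=items)
        for a, b in itertools.combinations(items, 2):
            dist = 0.1 if groups[a] == groups[b] else 1.0
            d.loc[a, b] = d.loc[b, a] = dist
        return d

    def test_separated_blobs_recovered(self):
        groups = {f"g{i}": i // 4 for i in range(8)}
        truth = Partition(groups)
        sim = cluster_and_score(self._blob_distances(groups), truth, k=2)
        assert sim == pytest.approx(1.0)

    def test_noise_distances_score_below_one(self):
        rng = np.random.default_rng(0)
        items = [f"g{i}" for i in range(12)]
        truth = Partition({g: i // 4 for i, g in enumerate(items)})
        sims = []
        for rep in range(5):
            sq = rng.uniform(0.2, 1.0, size=(12, 12))
            sq = (sq + sq.T) / 2
            np.fill_diagonal(sq, 0.0)
            d = pd.DataFrame(sq, index=items, columns=items)
            sims.append(cluster_and_score(d, truth, k=3))
        assert np.mean(sims) < 0.6

    def test_equal_distances_deterministic(self):
        items = [f"g{i}" for i in range(6)]
        truth = Partition({g: i % 2 for i, g in enumerate(items)})
        d = pd.DataFrame(1.0, index=items, columns=items)
        np.fill_diagonal(d.values, 0.0)
        first = cluster_and_score(d, truth, k=2)
        assert all(cluster_and_score(d, truth, k=2) == first for _ in range(3))

    def test_incomplete_matrix_rejected(self):
        items = ["a", "b", "c"]
        d = pd.DataFrame(np.nan, index=items, columns=items)
        with pytest.raises(DomainError):
            cluster_and_score(d, Partition({i: 0 for i in items}), k=2)


def _dist(name, values):
    return PerformanceDistribution(name, "auc", np.asarray(values, dtype=float))


class TestRanking:
    def test_exhausted_ranks_on_statistical_tie(self):
        rng = np.random.default_rng(0)
        a = _dist("a", 0.90 + rng.normal(0, 0.05, 40))
        b = _dist("b", 0.89 + rng.normal(0, 0.05, 40))
        c = _dist("c", 0.70 + rng.normal(0, 0.01, 40))
        ranks = rank_with_ties([c, a, b])
        assert ranks == {"a": 1, "b": 1, "c": 3}

    def test_all_distinct(self):
        dists = [_dist(n, np.full(10, mu) + np.linspace(0, 1e-3, 10))
                 for n, mu in [("x", 0.9), ("y", 0.8), ("z", 0.7)]]
        assert rank_with_ties(dists) == {"x": 1, "y": 2, "z": 3}

    def test_all_tied(self):
        rng = np.random.default_rng(1)
        dists = [_dist(n, 0.5 + rng.normal(0, 0.1, 30)) for n in "abc"]
        assert set(rank_with_ties(dists).values()) == {1}

    def test_zero_variance_fallback(self):
        a = _dist("a", np.full(5, 0.9))
        b = _dist("b", np.full(5, 0.9))
        c = _dist("c", np.full(5, 0.1))
        assert rank_with_ties([a, b, c]) == {"a": 1, "b": 1, "c": 3}

    def test_valid_competition_ranking_property(self):
        rng = np.random.default_rng(3)
        dists = [_dist(f"m{i}", rng.uniform(0, 1) + rng.normal(0, 0.02, 25))
                 for i in range(8)]
        ranks = rank_with_ties(dists)
        assert min(ranks.values()) == 1
        by_mean = sorted(dists, key=lambda d: -d.mean)
        rank_seq = [ranks[d.measure] for d in by_mean]
        assert rank_seq == sorted(rank_seq)
        for r in set(rank_seq):
            assert rank_seq.count(r) >= 1 and rank_seq.index(r) == r - 1


class TestFactorInfluence:
    def _table(self, seed=0, driven_by="ontology"):
        rng = np.random.default_rng(seed)
        rows = []
        effect = {"BP": 0.3, "MF": 0.0, "CC": -0.3}
        for ns in ("BP", "MF", "CC"):
            for ss in ("resnik", "lin", "jc"):
                for si in ("casi", "mica", "grasm", "agrasm", "sf"):
                    base = effect[ns] if driven_by == "ontology" else 0.0
                    rows.append((ns, ss, si, base + rng.normal(0, 0.03)))
        return pd.DataFrame(rows, columns=["ontology", "term_sim", "shared_info",
                                           "response"])

    def test_ontology_driven_response(self):
        out = factor_influence(self._table(seed=0))
        assert out["ontology"]["p"] < 0.01
        assert out["shared_info"]["p"] > 0.1
        assert out["ontology"]["neg_log10_p"] > 2

    def test_pure_noise_gives_large_p(self):
        ps = [factor_influence(self._table(seed=s, driven_by=None))["ontology"]["p"]
              for s in range(5)]
        assert max(ps) > 0.05  # not systematically significant

    def test_aliased_factors_rejected(self):
        df = self._table()
        df["dup"] = df["ontology"]
        with pytest.raises(ValidationError, match="aliased"):
            factor_influence(df)

    def test_single_level_factor_rejected(self):
        df = self._table()
        df["ontology"] = "BP"
        with pytest.raises(ValidationError):
            factor_influence(df)


class TestThresholdAndVoting:
    def test_worked_example(self):
        clf = train_threshold([0.9, 0.4, 0.8, 0.3], [1, 1, 0, 0])
        assert clf.threshold == pytest.approx(0.4)
        assert clf.f_score == pytest.approx(0.8)

    def test_separable_scores(self):
        clf = train_threshold([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert clf.f_score == 1.0
        assert clf.threshold == pytest.approx(0.8)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            train_threshold([0.1, 0.9], [1, 1])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 8, size=15).astype(float)
        labels = rng.integers(0, 2, size=15)
        if labels.min() == labels.max():
            return
        t, f = best_f_by_exhaustive_scan(scores.tolist(), labels.tolist())
        clf = train_threshold(scores, labels)
        assert clf.f_score == pytest.approx(f)
        assert clf.threshold == pytest.approx(t)

    def test_majority_vote_rules(self):
        clfs = [ThresholdClassifier(f"m{i}", 0.5, 1.0) for i in range(3)]
        scores = {"m0": [0.9], "m1": [0.9], "m2": [0.1]}
        assert majority_vote(clfs, scores)[0] == 1
        scores = {"m0": [0.9], "m1": [0.1], "m2": [0.1]}
        assert majority_vote(clfs, scores)[0] == 0
        two = clfs[:2]
        scores = {"m0": [0.9], "m1": [0.1]}
        assert majority_vote(two, scores)[0] == 0  # even split is negative

    def test_missing_panel_scores_rejected(self):
        clfs = [ThresholdClassifier("m0", 0.5, 1.0)]
        with pytest.raises(DomainError):
            majority_vote(clfs, {"other": [0.1]})


class TestCrossValidation:
    def _table(self, n=120, informative=True, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.tile([0, 1], n // 2)
        # separable case uses the labels themselves as scores: with a
        # continuous margin the smallest-threshold tie rule would park the
        # boundary on the training minimum of the positive class and the
        # global minimum positive would always cost one held-out error
        scores = labels.astype(float) if informative else rng.normal(0, 1, n)
        return PairScoreTable(pd.DataFrame({
            "id1": [f"a{i}" for i in range(n)],
            "id2": [f"b{i}" for i in range(n)],
            "label": labels,
            "m": scores,
        }))

    def test_separable_scores_zero_error(self):
        results = kfold_cv(self._table(informative=True), ["m"], k=5, seed=0)
        assert np.allclose(results["m"].replicates, 0.0)

    def test_uninformative_scores_near_half(self):
        results = kfold_cv(self._table(n=400, informative=False), ["m"], k=10, seed=1)
        d = results["m"]
        assert abs(d.mean - 0.5) <= 3 * max(d.sd / np.sqrt(d.B), 0.025)

    def test_fixed_seed_reproducible(self):
        t = self._table()
        a = kfold_cv(t, ["m"], k=5, seed=9)["m"].replicates
        b = kfold_cv(t, ["m"], k=5, seed=9)["m"].replicates
        assert np.array_equal(a, b)

    def test_panel_of_identical_members_matches_member(self):
        t = self._table()
        results = kfold_cv(t, ["m"], k=5, seed=0, panels={"vote": ["m", "m", "m"]})
        assert np.allclose(results["vote"].replicates, results["m"].replicates)

    def test_class_starved_split_fatal(self):
        df = pd.DataFrame({
            "id1": ["a1", "a2", "a3", "a4"],
            "id2": ["b1", "b2", "b3", "b4"],
            "label": [1, 0, 0, 0],
            "m": [0.9, 0.1, 0.2, 0.3],
        })
        with pytest.raises(ValidationError):
            kfold_cv(PairScoreTable(df), ["m"], k=4, seed=0)
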