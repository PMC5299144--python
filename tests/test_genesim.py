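import pytest
from hypothesis import given, settings, strategies as st

from gosemtk import (
    DomainError,
    GeneProfile,
    SharedInformation,
    ValidationError,
    aggregate,
    enumerate_measures,
    gene_profile,
    ic_table,
    measure_scorer,
    random_corpus,
    random_dag,
    sim_dic,
    sim_gic,
    sim_ui,
    sim_uic,
    term_similarity_function,
    toy1,
)
from gosemtk.genesim import MeasureConfig, jaccard_similarity


def _profile(g, terms):
    closure = set()
    for t in terms:
        closure |= g.ancestors(t, reflexive=True)
    return GeneProfile("x", frozenset(terms), frozenset(closure))


@pytest.fixture(scope="module")
def toy_setup():
    g, corpus = toy1()
    ic = ic_table(g, corpus, log_base=2)
    return g, corpus, ic


class TestAggregation:
    def test_bma_max_avg_worked_example(self, toy_setup):
        g, _corpus, ic = toy_setup
        sim = term_similarity_function(SharedInformation(g, ic), "lin")
        p1, p2 = _profile(g, {"E", "D"}), _profile(g, {"F"})
        assert aggregate(sim, p1, p2, "bma") == pytest.approx(0.625)
        assert aggregate(sim, p1, p2, "max") == pytest.approx(2 / 3)
        assert aggregate(sim, p1, p2, "avg") == pytest.approx(0.58333, abs=1e-5)

    def test_self_bma_is_one(self, toy_setup):
        g, _corpus, ic = toy_setup
        sim = term_similarity_function(SharedInformation(g, ic), "lin")
        p = _profile(g, {"E", "D"})
        assert aggregate(sim, p, p, "bma") == 1.0

    def test_symmetry_all_modes(self, toy_setup):
        g, _corpus, ic = toy_setup
        sim = term_similarity_function(SharedInformation(g, ic), "lin")
        p1, p2 = _profile(g, {"E", "B"}), _profile(g, {"F", "D"})
        for mode in ("max", "avg", "bma"):
            assert aggregate(sim, p1, p2, mode) == pytest.approx(
                aggregate(sim, p2, p1, mode))

    def test_bma_between_avg_and_max(self, toy_setup):
        g, _corpus, ic = toy_setup
        sim = term_similarity_function(SharedInformation(g, ic), "lin")
        p1, p2 = _profile(g, {"E", "D", "B"}), _profile(g, {"F", "C"})
        lo = aggregate(sim, p1, p2, "avg")
        hi = aggregate(sim, p1, p2, "max")
        assert lo - 1e-12 <= aggregate(sim, p1, p2, "bma") <= hi + 1e-12

    def test_unknown_mode_rejected(self, toy_setup):
        g, _corpus, ic = toy_setup
        sim = term_similarity_function(SharedInformation(g, ic), "lin")
        p = _profile(g, {"E"})
        with pytest.raises(DomainError):
            aggregate(sim, p, p, "median")


class TestJaccardFamily:
    def test_worked_examples(self, toy_setup):
        g, _corpus, ic = toy_setup
        pe, pf = _profile(g, {"E"}), _profile(g, {"F"})
        assert sim_ui(pe, pf) == pytest.approx(4 / 7)
        assert sim_gic(pe, pf, ic) == pytest.approx(0.26794, abs=1e-5)
        assert sim_dic(pe, pf, ic) == pytest.approx(0.42264, abs=1e-5)
        assert sim_uic(pe, pf, ic) == pytest.approx(0.37889, abs=1e-5)

    def test_root_only_overlap(self, toy_setup):
        g, corpus, ic = toy_setup
        # E and a hypothetical gene on B share {R, A, B}? no: E's closure
        # holds B; use D vs B which share {R, A}? D closure={D,A,R}, B={B,R}
        pd_, pb = _profile(g, {"D"}), _profile(g, {"B"})
        assert pd_.closure & pb.closure == {"R"}
        assert sim_gic(pd_, pb, ic) == 0.0
        assert sim_dic(pd_, pb, ic) == 0.0
        assert sim_ui(pd_, pb) > 0.0  # root always shared

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000), data=st.data())
    def test_properties_on_random_profiles(self, seed, data):
        """Symmetric, in [0,1], and 1 on identical profiles, for all four."""
        g = random_dag(n_terms=12, seed=seed % 50)
        corpus = random_corpus(g, n_genes=6, seed=seed)
        ic = ic_table(g, corpus)
        genes = sorted(corpus.genes("BP"))
        g1 = data.draw(st.sampled_from(genes))
        g2 = data.draw(st.sampled_from(genes))
        p1, p2 = gene_profile(g, corpus, g1), gene_profile(g, corpus, g2)
        for name in ("simui", "simgic", "simdic", "simuic"):
            v = jaccard_similarity(name, p1, p2, ic)
            assert 0.0 <= v <= 1.0 + 1e-12
            assert v == pytest.approx(jaccard_similarity(name, p2, p1, ic))
            assert jaccard_similarity(name, p1, p1, ic) == pytest.approx(1.0)
        assert sim_uic(p1, p2, ic) <= sim_dic(p1, p2, ic) + 1e-12


class TestEnumeration:
    def test_full_grid_counts(self):
        assert len(enumerate_measures()) == 45
        assert len(enumerate_measures(include_jaccard=True)) == 57

    def test_minimal_grid(self):
        assert len(enumerate_measures(["mica"], ["lin"], ["bma"])) == 3

    def test_unknown_names_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_measures(si_names=["mica", "bogus"])
        with pytest.raises(ValidationError):
            enumerate_measures(agg_names=[])


class TestScorer:
    def test_unannotated_gene_raises(self, toy_setup):
        g, corpus, _ic = toy_setup
        with pytest.raises(DomainError):
            gene_profile(g, corpus, "ghost")

    def test_scorer_matches_manual_aggregation(self, toy_setup):
        g, corpus, ic = toy_setup
        config = MeasureConfig(namespace="BP", si="mica", ss="lin", aggregator="bma")
        scorer = measure_scorer(config, g, ic, corpus)
        sim = term_similarity_function(SharedInformation(g, ic), "lin")
        p1 = gene_profile(g, corpus, "g1")
        p2 = gene_profile(g, corpus, "g2")
        assert scorer("g1", "g2") == pytest.approx(aggregate(sim, p1, p2, "bma"))

    def test_jaccard_scorer(self, toy_setup):
        g, corpus, ic = toy_setup
        config = MeasureConfig(namespace="BP", jaccard="simui")
        scorer = measure_scorer(config, g, ic, corpus)
        assert scorer("g1", "g2") == pytest.approx(4 / 7)  # genes on E and F
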