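import math

import numpy as np
import pytest

from herbnet.dmim import (
    CorpusIndex,
    EdgeRule,
    between_herb_distance,
    dmim_score,
    high_frequency_network,
    intersect_subnetworks,
    mutual_information,
    pair_score_table,
    seed_subnetwork,
    write_edge_tsv,
    write_graphml,
)

from conftest import make_corpus, random_corpus
from oracles import distance_oracle, mi_oracle, score_oracle


class TestMutualInformation:
    def test_perfect_cooccurrence_half_the_time(self):
        # x and y appear together in 2 of 4 formulae and never apart:
        # P(x)=P(y)=P(xy)=0.5 -> MI = 0.5 * log2(2) = 0.5 bits
        corpus = make_corpus(
            [["x", "y", "a"], ["x", "y", "b"], ["a", "b"], ["a", "c"]]
        )
        assert mutual_information(corpus, "x", "y") == pytest.approx(0.5)

    def test_independence_gives_zero(self):
        # P(xy) = 0.25 = P(x) P(y) exactly
        corpus = make_corpus(
            [["x", "y", "a"], ["x", "b", "c"], ["y", "b", "d"], ["a", "b"]]
        )
        assert mutual_information(corpus, "x", "y") == pytest.approx(0.0)

    def test_never_cooccurring_gives_zero(self):
        corpus = make_corpus([["x", "a"], ["y", "b"]])
        assert mutual_information(corpus, "x", "y") == 0.0

    def test_below_independence_clamped_or_negative(self):
        corpus = make_corpus(
            [["x", "a", "b"], ["y", "a", "c"], ["x", "y", "d"], ["x", "e", "f"],
             ["y", "e", "g"]]
        )
        clamped = mutual_information(corpus, "x", "y")
        raw = mutual_information(corpus, "x", "y", clamp=False)
        assert clamped >= 0.0
        assert raw <= clamped

    def test_same_herb_errors(self):
        with pytest.raises(ValueError):
            mutual_information(make_corpus([["x", "y"]]), "x", "x")


class TestBetweenHerbDistance:
    def test_single_cooccurrence(self):
        corpus = make_corpus([["a", "b", "x", "c", "d", "y"]])
        assert between_herb_distance(corpus, "x", "y") == pytest.approx(3.0)

    def test_mean_over_formulae(self):
        corpus = make_corpus([["x", "y", "a"], ["x", "a", "b", "y"]])
        assert between_herb_distance(corpus, "x", "y") == pytest.approx(2.0)

    def test_adjacent_everywhere_is_minimum(self):
        corpus = make_corpus([["x", "y", "a"], ["b", "x", "y"]])
        assert between_herb_distance(corpus, "x", "y") == pytest.approx(1.0)

    def test_no_cooccurrence_errors(self):
        with pytest.raises(ValueError, match="never co-occur"):
            between_herb_distance(make_corpus([["x", "a"], ["y", "b"]]), "x", "y")

    def test_normalized_distance_in_unit_interval(self):
        corpus = make_corpus([["x", "a", "b", "c", "y"]])
        d = between_herb_distance(corpus, "x", "y", normalize=True)
        assert d == pytest.approx(1.0)  # endpoints of the formula


class TestDmimScore:
    def test_quotient(self):
        # MI = 0.5 (perfect half-time cooccurrence), gap 3 in both formulae
        corpus = make_corpus(
            [
                ["x", "a", "b", "y"],
                ["x", "c", "d", "y"],
                ["a", "b"],
                ["a", "c"],
            ]
        )
        ps = dmim_score(corpus, "x", "y")
        assert ps.mi == pytest.approx(0.5)
        assert ps.d == pytest.approx(3.0)
        assert ps.score == pytest.approx(0.5 / 3)

    def test_zero_for_disjoint_pair(self):
        ps = dmim_score(make_corpus([["x", "a"], ["y", "b"]]), "x", "y")
        assert ps.score == 0.0 and ps.mi == 0.0 and math.isinf(ps.d)

    def test_symmetry(self, rng):
        corpus = random_corpus(rng, 8, 6)
        idx = CorpusIndex(corpus)
        herbs = sorted(idx.herbs)
        for i, x in enumerate(herbs):
            for y in herbs[i + 1:]:
                assert dmim_score(idx, x, y).score == pytest.approx(
                    dmim_score(idx, y, x).score, abs=1e-15
                )

    def test_matches_bruteforce_oracle(self, rng):
        # exhaustive recount on small random corpora, to 1e-12
        for _ in range(20):
            corpus = random_corpus(rng, int(rng.integers(2, 9)), 6)
            idx = CorpusIndex(corpus)
            herbs = sorted({h for p in corpus for h in p.herbs})
            for i, x in enumerate(herbs):
                for y in herbs[i + 1:]:
                    ps = dmim_score(idx, x, y)
                    assert ps.mi == pytest.approx(
                        mi_oracle(corpus, x, y), abs=1e-12
                    )
                    assert ps.score == pytest.approx(
                        score_oracle(corpus, x, y), abs=1e-12
                    )
                    if ps.support:
                        assert ps.d == pytest.approx(
                            distance_oracle(corpus, x, y), abs=1e-12
                        )


def _clique_corpus(herbs, n_with, n_without, filler_start=100):
    """Formulae where all ``herbs`` co-occur in ``n_with`` of the total."""
    formulae = []
    f = filler_start
    for _ in range(n_with):
        formulae.append(list(herbs) + [f"f{f}", f"f{f+1}"])
        f += 2
    for _ in range(n_without):
        formulae.append([f"f{f}", f"f{f+1}", f"f{f+2}"])
        f += 3
    return make_corpus(formulae)


class TestHighFrequencyNetwork:
    def test_planted_clique_is_complete(self):
        herbs = [f"t{i}" for i in range(10)]
        corpus = _clique_corpus(herbs, n_with=6, n_without=4)
        g = high_frequency_network(corpus, herbs)
        assert g.number_of_nodes() == 10
        assert g.number_of_edges() == 45  # C(10, 2)

    def test_missing_pair_drops_edge(self):
        corpus = make_corpus(
            [["a", "b", "x"], ["a", "b", "y"], ["b", "c", "z"], ["b", "c", "w"],
             ["a", "b", "u"], ["a", "b", "v"], ["b", "c", "q"], ["b", "c", "r"],
             ["a", "b", "s"], ["b", "c", "t"], ["x", "y"], ["z", "w"]]
        )
        g = high_frequency_network(corpus, ["a", "b", "c"], EdgeRule(min_support=5))
        assert g.has_edge("a", "b") and g.has_edge("b", "c")
        assert not g.has_edge("a", "c")
        assert g.number_of_edges() == 2

    def test_unreachable_threshold_gives_empty_edge_set(self):
        herbs = [f"t{i}" for i in range(10)]
        corpus = _clique_corpus(herbs, 6, 4)
        g = high_frequency_network(
            corpus, herbs, EdgeRule(score_threshold=1e9)
        )
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 10

    def test_needs_two_herbs(self):
        with pytest.raises(ValueError):
            high_frequency_network(make_corpus([["a", "b"]]), ["a"])


class TestSeedSubnetwork:
    def test_isolated_seed(self):
        # seed co-occurs too rarely with anything to pass min_support
        corpus = make_corpus([["s", "a"], ["b", "c"], ["b", "d"]])
        g = seed_subnetwork(corpus, "s", EdgeRule(min_support=5))
        assert set(g.nodes) == {"s"}
        assert g.number_of_edges() == 0

    def test_planted_module_recovered(self):
        module = ["s", "m1", "m2", "m3", "m4"]
        corpus = _clique_corpus(module, n_with=6, n_without=4)
        g = seed_subnetwork(corpus, "s")
        assert set(g.nodes) == set(module)

    def test_quantile_rule_prunes_weak_edges(self):
        module = ["s", "m1", "m2", "m3", "m4"]
        corpus = _clique_corpus(module, n_with=6, n_without=4)
        full = seed_subnetwork(corpus, "s")
        pruned = seed_subnetwork(corpus, "s", EdgeRule(quantile=0.99))
        assert pruned.number_of_nodes() <= full.number_of_nodes()
        assert "s" in pruned.nodes


class TestIntersectSubnetworks:
    def test_idempotent(self):
        corpus = _clique_corpus(["a", "b", "c"], 6, 2)
        g = high_frequency_network(corpus, ["a", "b", "c"])
        out = intersect_subnetworks([g, g])
        assert set(out.nodes) == set(g.nodes)
        assert set(map(frozenset, out.edges)) == set(map(frozenset, g.edges))

    def test_node_and_edge_intersection(self):
        import networkx as nx

        g1 = nx.Graph([("a", "b"), ("b", "c")])
        g2 = nx.Graph([("b", "c"), ("c", "d")])
        out = intersect_subnetworks([g1, g2])
        assert set(out.nodes) == {"b", "c"}
        assert set(map(frozenset, out.edges)) == {frozenset({"b", "c"})}

    def test_associative_and_order_invariant(self, rng):
        import networkx as nx

        graphs = []
        for _ in range(3):
            g = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(2**31)))
            graphs.append(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        a = intersect_subnetworks(graphs)
        b = intersect_subnetworks(graphs[::-1])
        c = intersect_subnetworks(
            [intersect_subnetworks(graphs[:2]), graphs[2]]
        )
        for other in (b, c):
            assert set(a.nodes) == set(other.nodes)
            assert set(map(frozenset, a.edges)) == set(map(frozenset, other.edges))

    def test_empty_intersection_is_valid(self, caplog):
        import networkx as nx

        out = intersect_subnetworks(
            [nx.Graph([("a", "b")]), nx.Graph([("c", "d")])]
        )
        assert out.number_of_nodes() == 0


class TestExports:
    def test_edge_tsv_and_graphml(self, tmp_path):
        corpus = _clique_corpus(["a", "b", "c"], 6, 2)
        g = high_frequency_network(corpus, ["a", "b", "c"])
        write_edge_tsv(g, tmp_path / "edges.tsv")
        write_graphml(g, tmp_path / "net.graphml")
        assert (tmp_path / "edges.tsv").read_text().startswith("herb_x\therb_y")
        assert (tmp_path / "net.graphml").stat().st_size > 0

    def test_pair_score_table_columns(self):
        corpus = _clique_corpus(["a", "b", "c"], 6, 2)
        df = pair_score_table(corpus, ["a", "b", "c"])
        assert list(df.columns) == ["herb_x", "herb_y", "mi", "d", "score", "support"]
        assert len(df) == 3
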