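import networkx as nx
import numpy as np
import pytest

from herbnet import reference
from herbnet.bridge import (
    build_bridge_network,
    link_predicate,
    property_enrichment,
    restrict_background,
    write_bridge_graphml,
    write_cluster_tsv,
)
from herbnet.targets import ReferenceDrug

from oracles import link_oracle


def drug(did, targets, cls="immunomodulatory"):
    return ReferenceDrug(
        id=did,
        fingerprint=np.zeros(8, dtype=np.uint8),
        targets=frozenset(targets),
        drug_class=cls,
    )


class TestRestrictBackground:
    def test_all_genes_keeps_whole_network(self):
        g = nx.path_graph(5)
        out = restrict_background(g, list(g.nodes))
        assert set(out.nodes) == set(g.nodes)
        assert out.number_of_edges() == g.number_of_edges()

    def test_single_gene_with_neighbors_is_star(self):
        g = nx.star_graph(3)  # center 0
        out = restrict_background(g, [0])
        assert set(out.nodes) == {0, 1, 2, 3}

    def test_genes_only_mode(self):
        g = nx.path_graph(5)
        out = restrict_background(g, [0, 1], include_neighbors=False)
        assert set(out.nodes) == {0, 1}

    def test_no_gene_in_network_errors(self):
        with pytest.raises(ValueError, match="no disease gene"):
            restrict_background(nx.path_graph(3), ["zz"])


class TestLinkPredicate:
    def setup_method(self):
        # p1 - p2 - p3 path: p1/p2 adjacent, p1/p3 two hops apart
        self.g = nx.path_graph(["p1", "p2", "p3"])

    def test_overlap_links(self):
        assert link_predicate({"p1"}, {"p1", "p2"}, self.g)

    def test_adjacency_links(self):
        assert link_predicate({"p1"}, {"p2"}, self.g)

    def test_two_hops_do_not_link(self):
        assert not link_predicate({"p1"}, {"p3"}, self.g)

    def test_symmetry_random(self, rng):
        g = nx.gnp_random_graph(8, 0.3, seed=int(rng.integers(2**31)))
        nodes = sorted(g.nodes)
        for _ in range(20):
            a = set(rng.choice(nodes, size=2, replace=False))
            b = set(rng.choice(nodes, size=2, replace=False))
            assert link_predicate(a, b, g) == link_predicate(b, a, g)


class TestBuildBridgeNetwork:
    def test_edges_match_bruteforce_predicate(self, rng):
        for _ in range(15):
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(2**31)))
            g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes})
            nodes = sorted(g.nodes)
            comp_targets = {
                f"h{j}:c0": set(
                    rng.choice(nodes, size=int(rng.integers(1, 4)), replace=False)
                )
                for j in range(4)
            }
            comp_herb = {cid: cid.split(":")[0] for cid in comp_targets}
            props = {f"h{j}": "Cold" for j in range(4)}
            drugs = [
                drug("d0", rng.choice(nodes, size=2, replace=False))
            ]
            net = build_bridge_network(comp_targets, comp_herb, props, drugs, g)
            all_targets = dict(comp_targets)
            all_targets["d0"] = set(drugs[0].targets)
            present = set(net.graph.nodes)
            for a in present:
                for b in present:
                    if a < b:
                        expected = link_oracle(
                            all_targets[a], all_targets[b], nodes, g.edges
                        )
                        assert net.graph.has_edge(a, b) == expected

    def test_no_edges_gives_singleton_clusters(self):
        g = nx.Graph()
        g.add_nodes_from(["t1", "t2", "t3"])
        comp_targets = {"h1:c0": {"t1"}, "h2:c0": {"t2"}}
        net = build_bridge_network(
            comp_targets,
            {"h1:c0": "h1", "h2:c0": "h2"},
            {"h1": "Cold", "h2": "Hot"},
            [drug("d0", {"t3"})],
            g,
        )
        assert net.graph.number_of_edges() == 0
        assert len(set(net.clusters.values())) == 3

    def test_shared_target_collapses_to_one_cluster(self):
        g = nx.Graph()
        g.add_node("t1")
        comp_targets = {"h1:c0": {"t1"}, "h2:c0": {"t1"}}
        net = build_bridge_network(
            comp_targets,
            {"h1:c0": "h1", "h2:c0": "h2"},
            {"h1": "Cold", "h2": "Hot"},
            [drug("d0", {"t1"})],
            g,
        )
        assert len(set(net.clusters.values())) == 1

    def test_clusters_partition_nodes(self, rng):
        g = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(2**31)))
        g = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes})
        nodes = sorted(g.nodes)
        comp_targets = {
            f"h{j}:c0": set(rng.choice(nodes, size=2, replace=False))
            for j in range(5)
        }
        net = build_bridge_network(
            comp_targets,
            {cid: cid.split(":")[0] for cid in comp_targets},
            {f"h{j}": "Warm" for j in range(5)},
            [drug("d0", rng.choice(nodes, size=2, replace=False))],
            g,
        )
        assert set(net.clusters) == set(net.graph.nodes)
        members = net.cluster_members()
        all_nodes = [n for ms in members.values() for n in ms]
        assert sorted(all_nodes) == sorted(net.graph.nodes)

    def test_node_without_background_targets_dropped(self, caplog):
        g = nx.Graph()
        g.add_node("t1")
        net = build_bridge_network(
            {"h1:c0": {"t1"}, "h2:c0": {"offgrid"}},
            {"h1:c0": "h1", "h2:c0": "h2"},
            {"h1": "Cold", "h2": "Hot"},
            [drug("d0", {"t1"})],
            g,
        )
        assert "h2:c0" not in net.graph.nodes


class TestPropertyEnrichment:
    def test_exact_fisher_probability_for_pure_cold_cluster(self):
        # 8 property-annotated herbs; the drug cluster holds exactly the 4
        # Cold ones -> one-sided P = 1 / C(8,4) = 1/70
        g = nx.Graph()
        g.add_nodes_from([f"t{i}" for i in range(9)])
        comp_targets = {}
        comp_herb = {}
        props = {}
        for j in range(4):  # Cold herbs share the drug's target
            cid = f"cold{j}:c0"
            comp_targets[cid] = {"t0"}
            comp_herb[cid] = f"cold{j}"
            props[f"cold{j}"] = "Cold"
        for j in range(4):  # Warm herbs isolated on their own targets
            cid = f"warm{j}:c0"
            comp_targets[cid] = {f"t{j + 1}"}
            comp_herb[cid] = f"warm{j}"
            props[f"warm{j}"] = "Warm"
        net = build_bridge_network(
            comp_targets, comp_herb, props, [drug("d0", {"t0"})], g
        )
        enr = property_enrichment(net, props)
        cold = enr[(enr.property == "Cold") & (enr.cluster == 0)].iloc[0]
        assert cold.p_raw == pytest.approx(1 / 70, abs=1e-12)
        assert np.isinf(cold.odds_ratio)

    def test_uniform_property_distribution_not_significant(self, rng):
        g = nx.Graph()
        g.add_node("t0")
        comp_targets, comp_herb, props = {}, {}, {}
        for j in range(8):
            cid = f"h{j}:c0"
            comp_targets[cid] = {"t0"}
            comp_herb[cid] = f"h{j}"
            props[f"h{j}"] = "Cold" if j % 2 == 0 else "Hot"
        net = build_bridge_network(
            comp_targets, comp_herb, props, [drug("d0", {"t0"})], g
        )
        enr = property_enrichment(net, props)
        # everyone is in the single cluster: no property can be enriched
        assert (enr.p_adj > 0.05).all()

    def test_reported_property_census_of_top_herbs(self):
        # the transcribed top-15 herb table carries the printed property
        # composition used as the default property universe
        counts = {}
        for _, _, prop, _, _ in reference.TOP15_HERBS:
            counts[prop] = counts.get(prop, 0) + 1
        assert counts == {"Warm": 4, "Neutral": 5, "Cold": 4, "Hot": 1, "Cool": 1}

    def test_no_drug_cluster_yields_empty_table(self):
        g = nx.Graph()
        g.add_nodes_from(["t0", "t1"])
        net = build_bridge_network(
            {"h1:c0": {"t0"}},
            {"h1:c0": "h1"},
            {"h1": "Cold"},
            [drug("d0", {"t1"})],
            g,
        )
        enr = property_enrichment(net, {"h1": "Cold"})
        # the drug sits alone in its cluster; only herb-bearing drug
        # clusters are testable
        assert (enr["cluster"] != net.clusters["d0"]).all() or enr.empty


class TestExports:
    def test_graphml_and_cluster_tsv(self, tmp_path):
        g = nx.Graph()
        g.add_node("t0")
        net = build_bridge_network(
            {"h1:c0": {"t0"}},
            {"h1:c0": "h1"},
            {"h1": "Cold"},
            [drug("d0", {"t0"})],
            g,
        )
        write_bridge_graphml(net, tmp_path / "b.graphml")
        write_cluster_tsv(net, tmp_path / "b.tsv")
        assert (tmp_path / "b.graphml").stat().st_size > 0
        df_text = (tmp_path / "b.tsv").read_text()
        assert "cluster" in df_text
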