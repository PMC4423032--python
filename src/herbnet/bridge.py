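"""Compound-drug bridge networks on a disease-restricted interactome.

The background network is the PPI subgraph induced by the disease genes
plus (by default) their first neighbors. Herbal compounds (each carrying
its predicted target set, restricted to the background) and reference
drugs (their known targets, likewise restricted) become nodes of a bridge
network; two nodes are linked when their target sets overlap or are
directly connected (share at least one PPI edge) on the background.

Clusters of the bridge network (connected components by default) are then
tested for association between the traditional property of the herbs they
contain (Cold/Hot/Warm/Cool/Neutral) and the class of the drugs they
contain (e.g. immunomodulatory vs hormone) via one-sided Fisher tests
with Benjamini-Hochberg correction — a statistical formalization of the
visual cluster-composition reading of the compound-drug maps.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .targets import ReferenceDrug

logger = logging.getLogger(__name__)


def restrict_background(
    ppi: nx.Graph,
    disease_genes: Iterable[str],
    *,
    include_neighbors: bool = True,
) -> nx.Graph:
    """PPI subgraph induced by disease genes (plus first neighbors by default)."""
    genes = set(disease_genes) & set(ppi.nodes)
    if not genes:
        raise ValueError("no disease gene is present in the PPI network")
    nodes = set(genes)
    if include_neighbors:
        for g in genes:
            nodes.update(ppi.neighbors(g))
    return ppi.subgraph(nodes).copy()


def link_predicate(
    targets_a: Iterable[str],
    targets_b: Iterable[str],
    background: nx.Graph,
) -> bool:
    """True iff the sets overlap or are adjacent (1 hop) on the background."""
    a = set(targets_a) & set(background.nodes)
    b = set(targets_b) & set(background.nodes)
    if a & b:
        return True
    for u in a:
        if not b.isdisjoint(background.neighbors(u)):
            return True
    return False


@dataclass
class BridgeNetwork:
    """Typed compound/drug network with a node partition into clusters."""

    graph: nx.Graph
    clusters: dict[str, int]  #: node -> cluster id (clusters partition nodes)

    def cluster_members(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for node, cid in self.clusters.items():
            out.setdefault(cid, set()).add(node)
        return out

    def cluster_table(self) -> pd.DataFrame:
        rows = [
            (
                node,
                cid,
                self.graph.nodes[node].get("kind"),
                self.graph.nodes[node].get("herb", ""),
                self.graph.nodes[node].get("property", ""),
                self.graph.nodes[node].get("drug_class", ""),
            )
            for node, cid in sorted(self.clusters.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["node", "cluster", "kind", "herb", "property", "drug_class"],
        )


def build_bridge_network(
    compound_targets: Mapping[str, Iterable[str]],
    compound_herb: Mapping[str, str],
    herb_properties: Mapping[str, str],
    drugs: Sequence[ReferenceDrug],
    background: nx.Graph,
    *,
    clustering: str = "components",
) -> BridgeNetwork:
    """Link compounds and drugs whose targets overlap or touch on the background.

    Nodes whose target sets vanish after restriction to the background are
    dropped with a warning. ``clustering`` is ``"components"`` (default) or
    ``"modularity"`` (greedy modularity communities).
    """
    if clustering not in ("components", "modularity"):
        raise ValueError("clustering must be 'components' or 'modularity'")
    bg_nodes = sorted(background.nodes)
    bg_index = {n: i for i, n in enumerate(bg_nodes)}
    adj = nx.to_numpy_array(background, nodelist=bg_nodes, dtype=np.int32)
    np.fill_diagonal(adj, 0)

    names: list[str] = []
    member = []  # boolean target membership per node
    attrs: dict[str, dict] = {}
    dropped = []
    for cid in sorted(compound_targets):
        vec = np.zeros(len(bg_nodes), dtype=np.int32)
        for t in compound_targets[cid]:
            i = bg_index.get(t)
            if i is not None:
                vec[i] = 1
        if vec.sum() == 0:
            dropped.append(cid)
            continue
        herb = compound_herb[cid]
        names.append(cid)
        member.append(vec)
        attrs[cid] = {
            "kind": "compound",
            "herb": herb,
            "property": herb_properties.get(herb, ""),
        }
    for drug in drugs:
        vec = np.zeros(len(bg_nodes), dtype=np.int32)
        for t in drug.targets:
            i = bg_index.get(t)
            if i is not None:
                vec[i] = 1
        if vec.sum() == 0:
            dropped.append(drug.id)
            continue
        names.append(drug.id)
        member.append(vec)
        attrs[drug.id] = {"kind": "drug", "drug_class": drug.drug_class}
    if dropped:
        logger.warning(
            "%d nodes dropped: no targets on the restricted background", len(dropped)
        )
    g = nx.Graph()
    for name in names:
        g.add_node(name, **attrs[name])
    if names:
        m = np.vstack(member)
        extended = ((m + m @ adj) > 0).astype(np.int32)  # targets plus 1-hop halo
        links = (m @ extended.T) > 0
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if links[i, j]:
                    g.add_edge(names[i], names[j])
    if clustering == "components":
        communities = list(nx.connected_components(g))
    else:
        communities = list(nx.community.greedy_modularity_communities(g))
    order = sorted(communities, key=lambda c: (-len(c), min(c)))
    clusters = {node: cid for cid, comm in enumerate(order) for node in comm}
    return BridgeNetwork(graph=g, clusters=clusters)


def property_enrichment(
    net: BridgeNetwork,
    herb_properties: Mapping[str, str],
) -> pd.DataFrame:
    """Herb-property composition tests for every drug-containing cluster.

    For each cluster holding at least one drug, and each property observed
    among the property-annotated herbs of the network, a one-sided Fisher
    test compares property counts of herbs inside vs outside the cluster
    (herbs deduplicated; a herb is inside if any of its compounds is). BH
    correction is applied across all tests. Infinite odds ratios are
    reported as ``inf``.
    """
    herbs_of_node = {
        n: d["herb"]
        for n, d in net.graph.nodes(data=True)
        if d.get("kind") == "compound"
    }
    universe = {
        h for h in set(herbs_of_node.values()) if herb_properties.get(h)
    }
    if not universe:
        return pd.DataFrame(
            columns=[
                "cluster", "property", "n_cluster_herbs", "k_property",
                "odds_ratio", "p_raw", "p_adj", "drug_classes",
            ]
        )
    properties = sorted({herb_properties[h] for h in universe})
    members = net.cluster_members()
    rows = []
    for cid in sorted(members):
        nodes = members[cid]
        drug_classes = sorted(
            {
                net.graph.nodes[n]["drug_class"]
                for n in nodes
                if net.graph.nodes[n].get("kind") == "drug"
            }
        )
        if not drug_classes:
            continue
        inside = {herbs_of_node[n] for n in nodes if n in herbs_of_node} & universe
        if not inside:
            continue  # drug-only cluster: no property composition to test
        outside = universe - inside
        for prop in properties:
            a = sum(1 for h in inside if herb_properties[h] == prop)
            b = len(inside) - a
            c = sum(1 for h in outside if herb_properties[h] == prop)
            d = len(outside) - c
            odds, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append(
                (cid, prop, len(inside), a, float(odds), float(p),
                 ",".join(drug_classes))
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster", "property", "n_cluster_herbs", "k_property",
            "odds_ratio", "p_raw", "drug_classes",
        ],
    )
    if len(df):
        df["p_adj"] = multipletests(df["p_raw"], method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    return df[
        [
            "cluster", "property", "n_cluster_herbs", "k_property",
            "odds_ratio", "p_raw", "p_adj", "drug_classes",
        ]
    ].sort_values(["p_adj", "p_raw", "cluster", "property"], ignore_index=True)


def write_bridge_graphml(net: BridgeNetwork, path: str | Path) -> None:
    g = net.graph.copy()
    for node, cid in net.clusters.items():
        g.nodes[node]["cluster"] = cid
    nx.write_graphml(g, path)


def write_cluster_tsv(net: BridgeNetwork, path: str | Path) -> None:
    net.cluster_table().to_csv(path, sep="\t", index=False)


def write_enrichment_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
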