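"""Directed gene–gene network topology analysis.

A curated regulatory network is consumed as a directed edge list
(source, target, optional effect/category columns).  The analysis extracts
the strongly connected component — the maximal subnetwork in which every
gene is reachable from every other — and characterizes its genes with
NetworkAnalyzer-style topology metrics: in-/out-degree and directed
betweenness, plus clustering coefficient and neighborhood connectivity on
the undirected projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

import networkx as nx
import pandas as pd


class NetworkError(ValueError):
    pass


@dataclass
class DirectedNetwork:
    graph: nx.DiGraph
    n_self_loops_dropped: int = 0
    n_duplicates_collapsed: int = 0

    @property
    def nodes(self) -> List[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "effect": d.get("effect", "unspecified")}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "effect"])


def build_network(edges: pd.DataFrame,
                  node_attributes: Optional[Dict[str, str]] = None,
                  categories: Optional[Iterable[str]] = None) -> DirectedNetwork:
    """Build a directed network from an edge table.

    Self-loops are dropped and duplicate directed pairs collapsed (both
    counted).  ``node_attributes`` maps gene -> methylation direction
    ('hypo'/'hyper'/'mixed'); ``categories`` filters on an optional
    ``category`` column.
    """
    required = {"source", "target"}
    if not required <= set(edges.columns):
        raise NetworkError("edge table needs 'source' and 'target' columns")
    if categories is not None and "category" in edges.columns:
        edges = edges[edges["category"].isin(set(categories))]
    g = nx.DiGraph()
    self_loops = 0
    dups = 0
    for _, row in edges.iterrows():
        u, v = str(row["source"]), str(row["target"])
        if not u or not v:
            raise NetworkError(f"malformed edge row: {row.to_dict()}")
        if u == v:
            self_loops += 1
            continue
        if g.has_edge(u, v):
            dups += 1
            continue
        g.add_edge(u, v, effect=str(row["effect"]) if "effect" in edges.columns else "unspecified")
    if node_attributes:
        for node, direction in node_attributes.items():
            if node in g:
                g.nodes[node]["direction"] = direction
    return DirectedNetwork(graph=g, n_self_loops_dropped=self_loops,
                           n_duplicates_collapsed=dups)


def load_edge_list(path, node_attributes: Optional[Dict[str, str]] = None,
                   categories: Optional[Iterable[str]] = None) -> DirectedNetwork:
    """Load a directed edge list from TSV (columns source/target[/effect/category])."""
    try:
        edges = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # noqa: BLE001
        raise NetworkError(f"cannot parse edge list {path}: {exc}") from exc
    if edges.isna().any().any():
        bad = int(edges.isna().any(axis=1).idxmax()) + 2  # header is line 1
        raise NetworkError(f"malformed row at line {bad} of {path}")
    return build_network(edges, node_attributes=node_attributes, categories=categories)


def strongly_connected_components(net: DirectedNetwork) -> List[Set[str]]:
    """All SCCs (mutual-reachability classes) of the network."""
    return [set(c) for c in nx.strongly_connected_components(net.graph)]


def extract_scc(net: DirectedNetwork) -> Optional[DirectedNetwork]:
    """Induced subgraph of the unique nontrivial SCC.

    Returns None when no component has >= 2 nodes; warns and returns the
    largest when several nontrivial components exist.
    """
    comps = [c for c in strongly_connected_components(net) if len(c) >= 2]
    if not comps:
        return None
    if len(comps) > 1:
        warnings.warn(f"{len(comps)} nontrivial SCCs found; returning the largest")
    comps.sort(key=lambda c: (-len(c), sorted(c)[0]))
    sub = net.graph.subgraph(comps[0]).copy()
    return DirectedNetwork(graph=sub)


def topology_metrics(net: DirectedNetwork) -> pd.DataFrame:
    """Per-node topology metrics.

    In-/out-degree and betweenness (Brandes, normalized by (N-1)(N-2)) are
    computed on the directed graph; clustering coefficient and neighborhood
    connectivity follow the NetworkAnalyzer convention of the undirected
    projection: CC(v) = 2 e(N(v)) / (k_v (k_v - 1)) and neighborhood
    connectivity is the mean undirected degree of v's neighbors.
    """
    g = net.graph
    und = g.to_undirected()
    betweenness = nx.betweenness_centrality(g, normalized=g.number_of_nodes() > 2)
    clustering = nx.clustering(und)
    neigh = nx.average_neighbor_degree(und)
    rows = []
    for v in sorted(g.nodes):
        k_und = und.degree(v)
        rows.append({
            "gene": v,
            "in_degree": g.in_degree(v),
            "out_degree": g.out_degree(v),
            "betweenness": betweenness[v],
            "clustering_coefficient": clustering[v] if k_und >= 2 else 0.0,
            "neighborhood_connectivity": neigh[v] if k_und >= 1 else 0.0,
        })
    return pd.DataFrame(rows).set_index("gene")


def rank_hub_genes(metrics: pd.DataFrame) -> List[str]:
    """Genes ordered by total degree, ties by betweenness then name."""
    total = metrics["in_degree"] + metrics["out_degree"]
    order = sorted(
        metrics.index,
        key=lambda v: (-total[v], -metrics.loc[v, "betweenness"], v),
    )
    return order


def scc_partition_bruteforce(net: DirectedNetwork) -> List[Set[str]]:
    """O(n^3) SCC partition via transitive closure; reference oracle for
    small graphs."""
    nodes = list(net.graph.nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    reach = [[False] * n for _ in range(n)]
    for i in range(n):
        reach[i][i] = True
    for u, v in net.graph.edges:
        reach[idx[u]][idx[v]] = True
    for k in range(n):
        rk = reach[k]
        for i in range(n):
            if reach[i][k]:
                ri = reach[i]
                for j in range(n):
                    if rk[j]:
                        ri[j] = True
    seen = set()
    comps = []
    for i in range(n):
        if i in seen:
            continue
        comp = {nodes[i]}
        seen.add(i)
        for j in range(n):
            if j != i and reach[i][j] and reach[j][i]:
                comp.add(nodes[j])
                seen.add(j)
        comps.append(comp)
    return comps
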