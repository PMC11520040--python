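"""Signed co-occurrence network construction, topology panel, modules and
centralities.

Edges are taxon pairs whose basis-correlation magnitude exceeds a threshold
(optionally also passing a bootstrap significance cut), labelled by sign.
Topology statistics follow the usual co-occurrence panel: node/edge counts,
positive/negative edge split, diameter and average path length (unweighted,
on the largest connected component), average degree, signed weighted
degree, Louvain modularity and module count, and average clustering.

Heavy metrics run through igraph; the container is a networkx graph.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd

from .sparcc import CorrelationResult

__all__ = [
    "SignedNetwork",
    "TopologySummary",
    "ModulePartition",
    "build_network",
    "topology_summary",
    "detect_modules",
    "centralities",
    "write_edgelist_csv",
    "read_edgelist_csv",
]

#: sentinel for path metrics on edgeless graphs
UNDEFINED = float("nan")


@dataclass
class SignedNetwork:
    """Undirected signed graph over all taxa; nodes with >= 1 edge are the
    *connected* subset on which most statistics are computed."""

    graph: nx.Graph
    threshold: float
    provenance: str = ""

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def connected_nodes(self) -> list[str]:
        return [n for n, d in self.graph.degree() if d > 0]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_set(self) -> set[tuple[str, str, int]]:
        """Unordered edges as (min, max, sign) triples."""
        out = set()
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.add((a, b, d["sign"]))
        return out

    def subgraph_connected(self) -> nx.Graph:
        return self.graph.subgraph(self.connected_nodes).copy()

    def remove_node(self, taxon: str) -> "SignedNetwork":
        """Graph-level node deletion; surviving edge weights are untouched."""
        if taxon not in self.graph:
            raise KeyError(f"taxon {taxon!r} not in network")
        g = self.graph.copy()
        g.remove_node(taxon)
        return SignedNetwork(graph=g, threshold=self.threshold,
                             provenance=f"{self.provenance}-minus-{taxon}")


@dataclass
class TopologySummary:
    n_nodes_connected: int
    n_nodes_total: int
    n_edges: int
    n_pos: int
    n_neg: int
    pct_pos: float
    pct_neg: float
    diameter: float
    avg_degree: float
    weighted_degree: float
    avg_path_length: float
    modularity_Q: float
    n_modules: int
    avg_clustering: float

    def to_series(self) -> pd.Series:
        return pd.Series(vars(self))


@dataclass
class ModulePartition:
    assignment: dict[str, int]
    Q: float
    resolution: float
    seed: int

    @property
    def n_modules(self) -> int:
        return len(set(self.assignment.values()))

    def members(self, module: int) -> list[str]:
        return [n for n, m in self.assignment.items() if m == module]


def build_network(
    corr: CorrelationResult,
    threshold: float = 0.7,
    use_pvals: bool = False,
    alpha: float = 0.05,
) -> SignedNetwork:
    """Threshold a correlation matrix into a signed network.

    An edge is kept for every pair with ``|rho| > threshold`` (strict), and,
    when ``use_pvals`` is set, bootstrap p <= ``alpha``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    if use_pvals and corr.pvals is None:
        raise ValueError("use_pvals requested but correlation result has no p-values")
    g = nx.Graph()
    g.add_nodes_from(corr.taxon_ids)
    rho = corr.rho
    iu = np.triu_indices(rho.shape[0], 1)
    keep = np.abs(rho[iu]) > threshold
    if use_pvals:
        keep &= corr.pvals[iu] <= alpha
    for i, j in zip(iu[0][keep], iu[1][keep]):
        w = float(rho[i, j])
        g.add_edge(corr.taxon_ids[i], corr.taxon_ids[j],
                   weight=w, sign=1 if w > 0 else -1)
    return SignedNetwork(graph=g, threshold=threshold, provenance=f"seed={corr.seed}")


def _to_igraph(g: nx.Graph) -> tuple[ig.Graph, list[str]]:
    nodes = list(g.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    h = ig.Graph(n=len(nodes), edges=edges)
    h.es["weight"] = [d["weight"] for _, _, d in g.edges(data=True)]
    h.es["abs_weight"] = [abs(w) for w in h.es["weight"]]
    return h, nodes


def detect_modules(
    net: SignedNetwork, resolution: float = 1.0, seed: int = 0
) -> ModulePartition:
    """Louvain community detection on absolute edge weights.

    Louvain runs on the connected subgraph; singleton components (isolated
    nodes) each form their own module, as in the usual network-viewer
    convention of single-node modules.  Modularity Q is reported on the same
    |weight| graph.  Deterministic under ``seed``.
    """
    sub = net.subgraph_connected()
    if sub.number_of_edges() == 0:
        raise ValueError("module detection needs at least one edge")
    h, nodes = _to_igraph(sub)
    ig.set_random_number_generator(random.Random(seed))
    comm = h.community_multilevel(weights="abs_weight", resolution=resolution)
    membership = comm.membership
    q = h.modularity(membership, weights="abs_weight", resolution=resolution)
    assignment = {n: int(m) for n, m in zip(nodes, membership)}
    # dense module ids from 0, stable by first appearance
    remap: dict[int, int] = {}
    for n in nodes:
        m = assignment[n]
        if m not in remap:
            remap[m] = len(remap)
        assignment[n] = remap[m]
    # isolated nodes: one singleton module each
    next_id = len(remap)
    for n in net.graph.nodes:
        if n not in assignment:
            assignment[n] = next_id
            next_id += 1
    return ModulePartition(assignment=assignment, Q=float(q),
                           resolution=resolution, seed=seed)


def topology_summary(
    net: SignedNetwork,
    partition: ModulePartition | None = None,
    resolution: float = 1.0,
    seed: int = 0,
) -> TopologySummary:
    """Standard topology panel for a signed co-occurrence network.

    Diameter and average path length are unweighted and computed on the
    largest connected component; degree statistics are over connected nodes.
    """
    g = net.subgraph_connected()
    n_total = net.graph.number_of_nodes()
    n_conn = g.number_of_nodes()
    n_edges = g.number_of_edges()
    if n_edges == 0:
        return TopologySummary(0, n_total, 0, 0, 0, UNDEFINED, UNDEFINED,
                               UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED,
                               UNDEFINED, 0, UNDEFINED)
    signs = [d["sign"] for _, _, d in g.edges(data=True)]
    n_pos = sum(1 for s in signs if s > 0)
    n_neg = n_edges - n_pos
    h, nodes = _to_igraph(g)
    comps = h.connected_components()
    lcc = h.subgraph(max(comps, key=len))
    diameter = float(lcc.diameter(unconn=False))
    apl = float(lcc.average_path_length(unconn=False))
    if partition is None:
        partition = detect_modules(net, resolution=resolution, seed=seed)
    wdeg = [sum(d["weight"] for _, _, d in g.edges(n, data=True)) for n in g.nodes]
    return TopologySummary(
        n_nodes_connected=n_conn,
        n_nodes_total=n_total,
        n_edges=n_edges,
        n_pos=n_pos,
        n_neg=n_neg,
        pct_pos=100.0 * n_pos / n_edges,
        pct_neg=100.0 * n_neg / n_edges,
        diameter=diameter,
        avg_degree=2.0 * n_edges / n_conn,
        weighted_degree=float(np.mean(wdeg)),
        avg_path_length=apl,
        modularity_Q=partition.Q,
        n_modules=partition.n_modules,
        avg_clustering=float(np.mean(h.transitivity_local_undirected(mode="zero"))),
    )


def centralities(net: SignedNetwork) -> pd.DataFrame:
    """Per-node centrality table over *all* nodes of the network.

    degree: unweighted edge count; weighted_degree: signed sum of incident
    weights; betweenness/closeness: unweighted, per component; eigenvector:
    leading eigenvector of the |weight| adjacency of the largest connected
    component, scaled to max 1 (nodes outside the LCC get 0).
    """
    g = net.subgraph_connected()
    all_nodes = net.nodes
    out = pd.DataFrame(
        0.0,
        index=all_nodes,
        columns=["degree", "weighted_degree", "betweenness", "closeness", "eigenvector"],
    )
    if g.number_of_edges() == 0:
        out["degree"] = out["degree"].astype(int)
        return out
    h, nodes = _to_igraph(g)
    out.loc[nodes, "degree"] = h.degree()
    out.loc[nodes, "weighted_degree"] = [
        sum(d["weight"] for _, _, d in g.edges(n, data=True)) for n in nodes
    ]
    out.loc[nodes, "betweenness"] = h.betweenness()
    closeness = h.closeness()  # per component (unreachable pairs ignored)
    out.loc[nodes, "closeness"] = [0.0 if np.isnan(c) else c for c in closeness]
    comps = h.connected_components()
    lcc_idx = max(comps, key=len)
    lcc = h.subgraph(lcc_idx)
    ev = lcc.eigenvector_centrality(weights="abs_weight", scale=True)
    for local, vid in enumerate(lcc_idx):
        out.loc[nodes[vid], "eigenvector"] = ev[local]
    out["degree"] = out["degree"].astype(int)
    return out


def write_edgelist_csv(net: SignedNetwork, path) -> None:
    rows = [
        {"source": min(u, v), "target": max(u, v), "weight": d["weight"], "sign": d["sign"]}
        for u, v, d in net.graph.edges(data=True)
    ]
    df = pd.DataFrame(rows, columns=["source", "target", "weight", "sign"])
    df.sort_values(["source", "target"]).to_csv(path, index=False)


def read_edgelist_csv(path, nodes: list[str] | None = None,
                      threshold: float = 0.0) -> SignedNetwork:
    df = pd.read_csv(path)
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    for row in df.itertuples(index=False):
        g.add_edge(str(row.source), str(row.target),
                   weight=float(row.weight), sign=int(row.sign))
    return SignedNetwork(graph=g, threshold=threshold, provenance=str(path))
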