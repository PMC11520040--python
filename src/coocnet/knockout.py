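"""Ego sub-networks for a focal taxon and the in-silico removal experiment.

The ego sub-network lists every taxon the focal taxon is correlated with at
the network's threshold (its interaction partners), optionally with the
edges among partners.  The removal experiment compares the community
network before and after eliminating a focal taxon, in two modes:
``delete`` drops the node from the fixed network (surviving edges keep
their weights); ``reestimate`` drops the taxon's counts and re-runs the
whole inference chain, since compositional correlation estimates are not
strictly deletion-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from difflib import get_close_matches

from .network import (
    SignedNetwork,
    build_network,
    centralities,
    detect_modules,
    topology_summary,
)
from .prep import FeatureTable
from .sparcc import estimate_basis_correlations

__all__ = ["EgoSubnetwork", "ego_subnetwork", "remove_taxon_and_recompute"]


@dataclass
class EgoSubnetwork:
    focal: str
    partners: list[str]
    weights: dict[str, float]           # partner -> edge weight with focal
    partner_edges: list[tuple[str, str, float]] = field(default_factory=list)
    source: str = ""

    @property
    def n_positive(self) -> int:
        return sum(1 for w in self.weights.values() if w > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for w in self.weights.values() if w < 0)


def ego_subnetwork(
    net: SignedNetwork, taxon: str, include_partner_edges: bool = False
) -> EgoSubnetwork:
    """All taxa the focal taxon is correlated with at the network threshold."""
    if taxon not in net.graph:
        near = get_close_matches(taxon, list(net.graph.nodes), n=3)
        raise KeyError(f"taxon {taxon!r} not in network; close matches: {near}")
    partners = sorted(net.graph.neighbors(taxon))
    weights = {p: float(net.graph[taxon][p]["weight"]) for p in partners}
    partner_edges = []
    if include_partner_edges:
        pset = set(partners)
        for u, v, d in net.graph.edges(data=True):
            if u in pset and v in pset:
                a, b = sorted((u, v))
                partner_edges.append((a, b, float(d["weight"])))
    return EgoSubnetwork(
        focal=taxon, partners=partners, weights=weights,
        partner_edges=sorted(partner_edges), source=net.provenance,
    )


def _stage_bundle(net: SignedNetwork, seed: int) -> dict:
    part = detect_modules(net, seed=seed)
    return {
        "network": net,
        "partition": part,
        "topology": topology_summary(net, partition=part),
        "centralities": centralities(net),
    }


def remove_taxon_and_recompute(
    table: FeatureTable,
    taxon: str,
    mode: str = "delete",
    threshold: float = 0.7,
    seed: int = 0,
    sparcc_kwargs: dict | None = None,
    baseline: dict | None = None,
) -> dict:
    """Before/after bundle for the in-silico removal of one taxon.

    ``mode='delete'``: the taxon's node is deleted from the network inferred
    on the full table.  ``mode='reestimate'``: the taxon's counts are
    dropped and correlations, network, modules and centralities are
    re-estimated from scratch.  Returns a dict with ``before``/``after``
    stage bundles (network, partition, topology, centralities) and a
    ``deltas`` summary.  A precomputed ``baseline`` bundle (from a previous
    call) can be passed to avoid re-running the inference.
    """
    if taxon not in table.taxon_ids:
        raise KeyError(f"taxon {taxon!r} not in feature table")
    kwargs = sparcc_kwargs or {}
    if baseline is None:
        corr = estimate_basis_correlations(table, seed=seed, **kwargs)
        before = _stage_bundle(build_network(corr, threshold), seed)
    else:
        before = baseline
    if mode == "delete":
        after_net = before["network"].remove_node(taxon)
    elif mode == "reestimate":
        reduced = table.drop_taxa([taxon])
        corr2 = estimate_basis_correlations(reduced, seed=seed, **kwargs)
        after_net = build_network(corr2, threshold)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    after = _stage_bundle(after_net, seed)

    tb, ta = before["topology"], after["topology"]
    deltas = {
        "mode": mode,
        "taxon": taxon,
        "n_nodes_connected": ta.n_nodes_connected - tb.n_nodes_connected,
        "n_edges": ta.n_edges - tb.n_edges,
        "n_modules": ta.n_modules - tb.n_modules,
        "lcc_size_before": _lcc_size(before["network"]),
        "lcc_size_after": _lcc_size(after["network"]),
    }
    return {"before": before, "after": after, "deltas": deltas}


def _lcc_size(net: SignedNetwork) -> int:
    import networkx as nx

    g = net.subgraph_connected()
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(g))
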