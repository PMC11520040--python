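"""Cross-network comparison statistics.

Implements the panel used to compare co-occurrence networks between two
host groups: the core association network (edges shared with consistent
sign), a differential network (Fisher z-test on correlation differences
with Benjamini-Hochberg control), Jaccard similarity of top-quartile
centrality sets with two-sided hypergeometric tail probabilities, the
adjusted Rand index between module partitions with a permutation p-value,
a module-equivalence table (shared-over-union percentages for every module
pair), and partner-overlap counts for a focal taxon's ego sub-networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .network import ModulePartition, SignedNetwork
from .sparcc import CorrelationResult

__all__ = [
    "JaccardResult",
    "CANResult",
    "DiffNetResult",
    "core_association_network",
    "differential_network",
    "jaccard_centrality",
    "adjusted_rand_index",
    "module_equivalence",
    "partner_overlap",
]


@dataclass
class JaccardResult:
    measure: str
    J: float
    p_le: float
    p_ge: float
    size_a: int
    size_b: int
    intersection: int
    universe: int


@dataclass
class CANResult:
    """Edges (and their endpoint nodes) present in every input network with
    a consistent sign."""

    nodes: set[str]
    edges: set[tuple[str, str, int]]  # (u, v, sign), u < v

    def to_network(self, threshold: float) -> SignedNetwork:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for u, v, s in self.edges:
            g.add_edge(u, v, weight=float(s), sign=s)
        return SignedNetwork(graph=g, threshold=threshold, provenance="CAN")


@dataclass
class DiffNetResult:
    """Taxon pairs whose basis correlations differ between two networks."""

    pairs: pd.DataFrame  # columns: taxon_a, taxon_b, rho_A, rho_B, z, p, p_adj
    alpha: float

    @property
    def significant(self) -> pd.DataFrame:
        return self.pairs[self.pairs["p_adj"] < self.alpha]


def core_association_network(nets: list[SignedNetwork]) -> CANResult:
    """Intersection of edges (same unordered pair, same sign) across all
    networks; nodes are the endpoints of the surviving edges."""
    if len(nets) < 2:
        raise ValueError("core association network needs at least 2 networks")
    common = nets[0].edge_set()
    for net in nets[1:]:
        common &= net.edge_set()
    shared_nodes = set(nets[0].nodes)
    for net in nets[1:]:
        shared_nodes &= set(net.nodes)
    if not shared_nodes:
        warnings.warn("networks share no taxa; core association network is empty")
    nodes = {u for u, _, _ in common} | {v for _, v, _ in common}
    return CANResult(nodes=nodes, edges=common)


def differential_network(
    corr_a: CorrelationResult,
    corr_b: CorrelationResult,
    n_a: int,
    n_b: int,
    alpha: float = 0.05,
) -> DiffNetResult:
    """Fisher z-test for correlation differences over all shared taxon pairs.

    Both correlations are z-transformed; the difference is referred to a
    normal with SE sqrt(1/(nA-3) + 1/(nB-3)); p-values are BH-adjusted over
    all shared pairs and pairs with adjusted p < alpha are significant.
    """
    if n_a <= 3 or n_b <= 3:
        raise ValueError("Fisher z-test needs more than 3 samples per group")
    shared = [t for t in corr_a.taxon_ids if t in set(corr_b.taxon_ids)]
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared taxa")
    ia = {t: i for i, t in enumerate(corr_a.taxon_ids)}
    ib = {t: i for i, t in enumerate(corr_b.taxon_ids)}
    se = np.sqrt(1.0 / (n_a - 3) + 1.0 / (n_b - 3))
    clip = 0.999999
    rows = []
    for i in range(len(shared)):
        for j in range(i + 1, len(shared)):
            u, v = shared[i], shared[j]
            ra = float(corr_a.rho[ia[u], ia[v]])
            rb = float(corr_b.rho[ib[u], ib[v]])
            z = (np.arctanh(np.clip(ra, -clip, clip))
                 - np.arctanh(np.clip(rb, -clip, clip))) / se
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append((u, v, ra, rb, z, p))
    df = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "rho_A", "rho_B", "z", "p"])
    if len(df):
        df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    return DiffNetResult(pairs=df, alpha=alpha)


def _top_quantile_set(values: pd.Series, quantile: float) -> set[str]:
    cut = values.quantile(quantile)
    return set(values.index[values > cut])


def jaccard_centrality(
    centr_a: pd.DataFrame,
    centr_b: pd.DataFrame,
    quantile: float = 0.75,
    measures: tuple[str, ...] = ("degree", "betweenness", "closeness", "eigenvector"),
) -> list[JaccardResult]:
    """Jaccard similarity of the most-central nodes between two networks.

    For each measure, A and B are the shared-universe nodes whose score lies
    above the within-network ``quantile`` (default 75th percentile); the
    ``hub taxa`` set requires the top quartile of degree, betweenness and
    closeness simultaneously.  The null holds both set sizes fixed and draws
    them independently from the shared universe, so the intersection is
    hypergeometric: ``p_le = P(X <= x)``, ``p_ge = P(X >= x)``.
    """
    if centr_a.empty or centr_b.empty:
        raise ValueError("empty centrality table")
    universe = sorted(set(centr_a.index) & set(centr_b.index))
    n_univ = len(universe)
    ca = centr_a.loc[universe]
    cb = centr_b.loc[universe]
    results = []

    def one(measure: str, set_a: set[str], set_b: set[str]) -> JaccardResult:
        x = len(set_a & set_b)
        union = len(set_a | set_b)
        j = x / union if union else float("nan")
        rv = stats.hypergeom(n_univ, len(set_a), len(set_b))
        return JaccardResult(
            measure=measure, J=j,
            p_le=float(rv.cdf(x)), p_ge=float(rv.sf(x - 1)),
            size_a=len(set_a), size_b=len(set_b),
            intersection=x, universe=n_univ,
        )

    for m in measures:
        a = _top_quantile_set(ca[m], quantile)
        b = _top_quantile_set(cb[m], quantile)
        if not a or not b:
            results.append(JaccardResult(m, float("nan"), float("nan"),
                                         float("nan"), len(a), len(b), 0, n_univ))
            continue
        results.append(one(m, a, b))
    hub_measures = ("degree", "betweenness", "closeness")
    hub_a = set.intersection(*[_top_quantile_set(ca[m], quantile) for m in hub_measures])
    hub_b = set.intersection(*[_top_quantile_set(cb[m], quantile) for m in hub_measures])
    if hub_a and hub_b:
        results.append(one("hub_taxa", hub_a, hub_b))
    else:
        results.append(JaccardResult("hub_taxa", float("nan"), float("nan"),
                                     float("nan"), len(hub_a), len(hub_b), 0, n_univ))
    return results


def adjusted_rand_index(
    part_a: ModulePartition | dict[str, int],
    part_b: ModulePartition | dict[str, int],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Chance-corrected agreement between two module partitions.

    Restricted to nodes present in both partitions; returns ``(ARI, p)``
    where p is a permutation p-value from ``n_perm`` node-label shuffles
    (+1 smoothing).
    """
    a = part_a.assignment if isinstance(part_a, ModulePartition) else part_a
    b = part_b.assignment if isinstance(part_b, ModulePartition) else part_b
    shared = sorted(set(a) & set(b))
    if len(shared) < 2:
        raise ValueError("fewer than 2 shared nodes between partitions")
    la = np.array([a[t] for t in shared])
    lb = np.array([b[t] for t in shared])
    ari = float(adjusted_rand_score(la, lb))
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if adjusted_rand_score(la, rng.permutation(lb)) >= ari:
            exceed += 1
    p = (exceed + 1.0) / (n_perm + 1.0)
    return ari, p


def module_equivalence(
    part_a: ModulePartition | dict[str, int],
    part_b: ModulePartition | dict[str, int],
) -> pd.DataFrame:
    """Shared-taxa percentage for every module pair.

    For module A of the first partition and B of the second (matched by
    taxon name), the percentage is ``100 * |A & B| / |A | B|`` rounded to
    one decimal; returned in long form with shared counts and sizes.
    """
    a = part_a.assignment if isinstance(part_a, ModulePartition) else part_a
    b = part_b.assignment if isinstance(part_b, ModulePartition) else part_b
    mods_a: dict[int, set[str]] = {}
    mods_b: dict[int, set[str]] = {}
    for t, m in a.items():
        mods_a.setdefault(m, set()).add(t)
    for t, m in b.items():
        mods_b.setdefault(m, set()).add(t)
    rows = []
    for ma, sa in sorted(mods_a.items()):
        for mb, sb in sorted(mods_b.items()):
            shared = len(sa & sb)
            union = len(sa | sb)
            rows.append(
                {
                    "module_a": ma,
                    "module_b": mb,
                    "size_a": len(sa),
                    "size_b": len(sb),
                    "shared": shared,
                    "pct_shared": round(100.0 * shared / union, 1) if union else 0.0,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class OverlapReport:
    """Venn triple for the partner sets of one focal taxon in two networks."""

    focal: str
    only_a: set[str]
    only_b: set[str]
    shared: set[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return len(self.only_a), len(self.only_b), len(self.shared)


def partner_overlap(sub_a, sub_b) -> OverlapReport:
    """Compare the interacting partners of the same focal taxon across two
    ego sub-networks (see :mod:`coocnet.knockout`)."""
    if sub_a.focal != sub_b.focal:
        raise ValueError(
            f"ego sub-networks have different focal taxa: "
            f"{sub_a.focal!r} vs {sub_b.focal!r}"
        )
    pa = set(sub_a.partners)
    pb = set(sub_b.partners)
    return OverlapReport(
        focal=sub_a.focal, only_a=pa - pb, only_b=pb - pa, shared=pa & pb
    )
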