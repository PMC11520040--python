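"""Network robustness: node-removal attack curves and node-addition growth.

Connectivity is measured as the number of unordered node pairs that can
reach each other; *connectivity loss* after removing a node set is one
minus the fraction of initially reachable pairs still reachable.  Attack
strategies: random (averaged over replicates with a normal-quantile CI
band), static degree and betweenness orders, and a cascading attack that
recomputes betweenness after every removal.  Growth adds nodes whose edge
counts are resampled from the host network's degree distribution, tracking
the largest-connected-component size and average path length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

from .network import SignedNetwork, _to_igraph

__all__ = [
    "AttackCurve",
    "AdditionCurve",
    "connectivity_loss",
    "attack",
    "fraction_to_loss",
    "delta_fraction",
    "node_addition",
    "compare_addition",
]

Z_CI = float(stats.norm.ppf(0.975))


@dataclass
class AttackCurve:
    strategy: str
    fractions_removed: np.ndarray
    loss: np.ndarray
    se: np.ndarray | None = None
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    reps: int = 1
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"strategy": self.strategy, "fraction_removed": self.fractions_removed,
             "loss": self.loss}
        )
        if self.se is not None:
            df["se"] = self.se
            df["ci_lo"] = self.ci_lo
            df["ci_hi"] = self.ci_hi
        return df


@dataclass
class AdditionCurve:
    steps: np.ndarray
    lcc_size: np.ndarray          # mean over reps
    avg_path_length: np.ndarray   # mean over reps
    lcc_reps: np.ndarray          # reps x steps
    apl_reps: np.ndarray          # reps x steps
    lcc_ci: np.ndarray | None = None   # 2 x steps bootstrap CI
    apl_ci: np.ndarray | None = None
    reps: int = 1
    seed: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"step": self.steps, "lcc_size": self.lcc_size,
             "avg_path_length": self.avg_path_length}
        )
        if self.lcc_ci is not None:
            df["lcc_lo"], df["lcc_hi"] = self.lcc_ci
            df["apl_lo"], df["apl_hi"] = self.apl_ci
        return df


def _reachable_pairs(h: ig.Graph) -> int:
    return sum(len(c) * (len(c) - 1) // 2 for c in h.connected_components())


def connectivity_loss(net: SignedNetwork, removal_order: list[str]) -> np.ndarray:
    """Loss sequence: entry k is the loss after removing the first k+1 nodes.

    ``loss_k = 1 - R_k / R_0`` with R the number of reachable unordered node
    pairs among the remaining nodes (R_0 on the intact connected subgraph).
    """
    g = net.subgraph_connected()
    unknown = [t for t in removal_order if t not in g]
    if unknown:
        raise KeyError(f"nodes not in connected subgraph: {unknown[:5]}")
    h, nodes = _to_igraph(g)
    index = {n: i for i, n in enumerate(nodes)}
    r0 = _reachable_pairs(h)
    if r0 == 0:
        raise ValueError("network has no reachable pairs")
    alive = np.ones(len(nodes), dtype=bool)
    losses = []
    for taxon in removal_order:
        alive[index[taxon]] = False
        sub = h.induced_subgraph(np.where(alive)[0])
        losses.append(1.0 - _reachable_pairs(sub) / r0)
    return np.asarray(losses)


def _loss_for_order_idx(h: ig.Graph, order: np.ndarray, r0: int) -> np.ndarray:
    n = h.vcount()
    alive = np.ones(n, dtype=bool)
    losses = np.empty(len(order))
    for k, v in enumerate(order):
        alive[v] = False
        sub = h.induced_subgraph(np.where(alive)[0])
        losses[k] = 1.0 - _reachable_pairs(sub) / r0
    return losses


def attack(
    net: SignedNetwork,
    strategy: str = "cascading",
    reps: int = 100,
    seed: int = 0,
) -> AttackCurve:
    """Attack curve for one removal strategy.

    ``degree`` and ``betweenness`` remove in decreasing static order (ties
    broken by node id); ``cascading`` recomputes betweenness after each
    removal; ``random`` averages ``reps`` uniformly random orders and
    attaches a per-point standard error with a 97.5%-quantile normal CI
    band.  Fractions are k / n_connected for k = 0 .. n_connected.
    """
    g = net.subgraph_connected()
    if g.number_of_nodes() < 3:
        raise ValueError("attack needs a connected set of at least 3 nodes")
    h, nodes = _to_igraph(g)
    n = len(nodes)
    r0 = _reachable_pairs(h)
    fractions = np.arange(n + 1) / n

    def static_order(scores: list[float]) -> np.ndarray:
        return np.array(
            sorted(range(n), key=lambda v: (-scores[v], nodes[v]))
        )

    if strategy == "degree":
        losses = _loss_for_order_idx(h, static_order(h.degree()), r0)
        curve = np.concatenate([[0.0], losses])
        return AttackCurve(strategy, fractions, curve, seed=seed)
    if strategy == "betweenness":
        losses = _loss_for_order_idx(h, static_order(h.betweenness()), r0)
        curve = np.concatenate([[0.0], losses])
        return AttackCurve(strategy, fractions, curve, seed=seed)
    if strategy == "cascading":
        alive = list(range(n))
        sub = h.copy()
        losses = []
        # sub keeps original vertex ids via a name attribute
        sub.vs["orig"] = list(range(n))
        while sub.vcount() > 0:
            bet = sub.betweenness()
            pick = min(
                range(sub.vcount()),
                key=lambda v: (-bet[v], nodes[sub.vs[v]["orig"]]),
            )
            sub.delete_vertices(pick)
            losses.append(1.0 - _reachable_pairs(sub) / r0)
        curve = np.concatenate([[0.0], losses])
        return AttackCurve(strategy, fractions, curve, seed=seed)
    if strategy == "random":
        rng = np.random.default_rng(seed)
        mat = np.empty((reps, n + 1))
        for r in range(reps):
            order = rng.permutation(n)
            mat[r] = np.concatenate([[0.0], _loss_for_order_idx(h, order, r0)])
        mean = mat.mean(axis=0)
        se = mat.std(axis=0, ddof=1) / np.sqrt(reps)
        return AttackCurve(
            strategy, fractions, mean, se=se,
            ci_lo=mean - Z_CI * se, ci_hi=mean + Z_CI * se,
            reps=reps, seed=seed,
        )
    raise ValueError(f"unknown strategy {strategy!r}")


def fraction_to_loss(curve: AttackCurve, target: float = 0.8) -> float:
    """Smallest grid fraction at which the loss reaches ``target``."""
    hits = np.where(curve.loss >= target)[0]
    if len(hits) == 0:
        warnings.warn(f"curve never reaches loss {target}; returning nan")
        return float("nan")
    return float(curve.fractions_removed[hits[0]])


def delta_fraction(
    curve_a: AttackCurve, curve_b: AttackCurve, target: float = 0.8
) -> float:
    """Difference (A - B) in percentage points of the node fraction needed
    to reach the target connectivity loss."""
    return 100.0 * (fraction_to_loss(curve_a, target) - fraction_to_loss(curve_b, target))


def node_addition(
    net: SignedNetwork,
    n_max: int = 1000,
    attach_rule: str = "empirical",
    reps: int = 20,
    seed: int = 0,
    record_steps: list[int] | None = None,
    fixed_m: int = 1,
) -> AdditionCurve:
    """Grow the network by adding nodes and track LCC size and path length.

    Each new node draws an edge count from the host network's empirical
    degree distribution (``attach_rule='empirical'``; ``'fixed'`` uses
    ``fixed_m``) and attaches to uniformly random distinct existing nodes.
    Metrics are recorded at ``record_steps`` (default: every step up to 20,
    then multiples matching a ~40-point grid) and averaged over replicates
    with 2.5/97.5% bootstrap percentile bands.
    """
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    g = net.subgraph_connected()
    if g.number_of_nodes() == 0:
        raise ValueError("cannot grow an empty network")
    h0, nodes = _to_igraph(g)
    degrees = np.array(h0.degree())
    if record_steps is None:
        stride = max(1, n_max // 40)
        record_steps = sorted({*range(1, min(20, n_max) + 1),
                               *range(stride, n_max + 1, stride), n_max})
    record_steps = sorted(set(record_steps))
    steps = np.array(record_steps)
    rng = np.random.default_rng(seed)
    lcc_mat = np.empty((reps, len(steps)))
    apl_mat = np.empty((reps, len(steps)))
    for r in range(reps):
        h = h0.copy()
        rec = 0
        for step in range(1, n_max + 1):
            if attach_rule == "empirical":
                m = int(rng.choice(degrees))
            elif attach_rule == "fixed":
                m = fixed_m
            else:
                raise ValueError(f"unknown attach_rule {attach_rule!r}")
            m = min(m, h.vcount())
            new = h.vcount()
            h.add_vertices(1)
            if m > 0:
                targets = rng.choice(new, size=m, replace=False)
                h.add_edges([(new, int(t)) for t in targets])
            if rec < len(steps) and step == steps[rec]:
                comps = h.connected_components()
                lcc = h.subgraph(max(comps, key=len))
                lcc_mat[r, rec] = lcc.vcount()
                apl_mat[r, rec] = lcc.average_path_length(unconn=False)
                rec += 1
    lcc_mean = lcc_mat.mean(axis=0)
    apl_mean = apl_mat.mean(axis=0)
    # bootstrap over replicates
    n_boot = 200
    if reps > 1:
        bi = rng.integers(reps, size=(n_boot, reps))
        lcc_bs = lcc_mat[bi].mean(axis=1)
        apl_bs = apl_mat[bi].mean(axis=1)
        lcc_ci = np.percentile(lcc_bs, [2.5, 97.5], axis=0)
        apl_ci = np.percentile(apl_bs, [2.5, 97.5], axis=0)
    else:
        lcc_ci = np.vstack([lcc_mean, lcc_mean])
        apl_ci = np.vstack([apl_mean, apl_mean])
    return AdditionCurve(
        steps=steps, lcc_size=lcc_mean, avg_path_length=apl_mean,
        lcc_reps=lcc_mat, apl_reps=apl_mat,
        lcc_ci=lcc_ci, apl_ci=apl_ci, reps=reps, seed=seed,
    )


def compare_addition(
    curve_a: AdditionCurve, curve_b: AdditionCurve, seed: int = 0
) -> pd.DataFrame:
    """Paired per-step comparison of two growth trajectories.

    Wilcoxon signed-rank over the common step grid for each metric (LCC
    size, average path length), BH adjustment across the metric family, and
    a bootstrap CI for the median per-step difference.
    """
    from statsmodels.stats.multitest import multipletests

    common = sorted(set(curve_a.steps) & set(curve_b.steps))
    if not common:
        raise ValueError("curves share no steps")
    ia = np.searchsorted(curve_a.steps, common)
    ib = np.searchsorted(curve_b.steps, common)
    rng = np.random.default_rng(seed)
    rows = []
    for name, va, vb in (
        ("lcc_size", curve_a.lcc_size[ia], curve_b.lcc_size[ib]),
        ("avg_path_length", curve_a.avg_path_length[ia], curve_b.avg_path_length[ib]),
    ):
        diff = va - vb
        if np.allclose(diff, 0.0):
            p = 1.0
            stat = 0.0
        else:
            stat, p = stats.wilcoxon(va, vb, zero_method="wilcox")
        boots = np.median(
            diff[rng.integers(len(diff), size=(500, len(diff)))], axis=1
        )
        rows.append(
            {"metric": name, "statistic": float(stat), "p": float(p),
             "median_diff": float(np.median(diff)),
             "ci_lo": float(np.percentile(boots, 2.5)),
             "ci_hi": float(np.percentile(boots, 97.5))}
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
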