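"""End-to-end pipeline: preparation -> correlation -> networks -> keystones
-> cross-group comparison -> robustness -> focal-taxon knockouts.

The pipeline runs the full comparative analysis for two (or more) sample
groups from one declarative :class:`RunConfig`, writes machine-readable
outputs for each stage, logs every stage with its parameters, and persists
a config snapshot so a run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare as cmp
from . import robustness as rb
from .keystone import identify_keystones
from .knockout import ego_subnetwork, remove_taxon_and_recompute
from .network import (
    build_network,
    centralities,
    detect_modules,
    topology_summary,
    write_edgelist_csv,
)
from .prep import (
    FeatureTable,
    clr_transform,
    collapse_to_genus,
    filter_rare,
    identify_contaminants,
)
from .sparcc import estimate_basis_correlations
from .synth import (
    GroundTruthSpec,
    make_ground_truth,
    read_fixture,
    simulate_counts,
    write_fixture,
)

logger = logging.getLogger("coocnet")

__all__ = ["RunConfig", "run_pipeline", "simulate_two_group_study"]


@dataclass
class RunConfig:
    """Declarative configuration for one comparative run.

    Every threshold of the standard analysis has a named key: edge
    threshold 0.7, keystone eigenvector threshold 0.75, rare-taxon floors
    (10 reads, 3 samples), contaminant score 0.1, top-centrality quantile
    0.75, target connectivity loss 0.8, CI quantile 0.975 and up to 1000
    added nodes.
    """

    fixture_dirs: dict[str, str] = field(default_factory=dict)  # group -> dir
    out_dir: str = "coocnet_out"
    edge_threshold: float = 0.7
    use_pvals: bool = False
    alpha: float = 0.05
    contaminant_threshold: float = 0.1
    min_total_reads: int = 10
    min_prevalence: int = 3
    clr_pseudocount: float = 0.5
    sparcc_inner: int = 20
    sparcc_exclude: int = 10
    sparcc_exclude_threshold: float = 0.1
    sparcc_pseudocount: float = 0.5
    bootstrap: int = 0              # 0 disables edge p-values
    keystone_ev_threshold: float = 0.75
    jaccard_quantile: float = 0.75
    attack_strategies: tuple[str, ...] = ("random", "degree", "betweenness", "cascading")
    attack_reps: int = 50
    target_loss: float = 0.8
    addition_n_max: int = 1000
    addition_reps: int = 10
    focal_taxa: tuple[str, ...] = ("g__Escherichia-Shigella", "g__Wolbachia")
    knockout_mode: str = "delete"
    seed: int = 0
    resolution: float = 1.0

    def __post_init__(self) -> None:
        self.attack_strategies = tuple(self.attack_strategies)
        self.focal_taxa = tuple(self.focal_taxa)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _prepare_group(table: FeatureTable, taxonomy: dict[str, str],
                   cfg: RunConfig) -> tuple[FeatureTable, list[str]]:
    contaminants: list[str] = []
    if table.is_control.any():
        contaminants = identify_contaminants(table, cfg.contaminant_threshold)
        table = table.drop_taxa(contaminants)
    table = collapse_to_genus(table, taxonomy)
    table = table.real_samples()
    table = filter_rare(table, cfg.min_total_reads, cfg.min_prevalence)
    return table, contaminants


def _group_stage(name: str, table: FeatureTable, taxonomy: dict[str, str],
                 cfg: RunConfig, seed: int) -> dict:
    t0 = time.time()
    prepared, contaminants = _prepare_group(table, taxonomy, cfg)
    clr = clr_transform(prepared, cfg.clr_pseudocount)
    corr = estimate_basis_correlations(
        prepared,
        n_inner=cfg.sparcc_inner,
        n_exclude=cfg.sparcc_exclude,
        exclude_threshold=cfg.sparcc_exclude_threshold,
        pseudocount=cfg.sparcc_pseudocount,
        seed=seed,
    )
    if cfg.bootstrap > 0:
        from .sparcc import bootstrap_pvalues

        corr.pvals = bootstrap_pvalues(prepared, corr, n_boot=cfg.bootstrap,
                                       seed=seed + 1)
    net = build_network(corr, cfg.edge_threshold,
                        use_pvals=cfg.bootstrap > 0 and cfg.use_pvals,
                        alpha=cfg.alpha)
    part = detect_modules(net, resolution=cfg.resolution, seed=seed)
    topo = topology_summary(net, partition=part)
    centr = centralities(net)
    keystones = identify_keystones(prepared, clr, centr,
                                   cfg.keystone_ev_threshold)
    logger.info("group %s: %d taxa, %d contaminants removed, %d edges, "
                "%d modules (%.1fs)", name, prepared.n_taxa,
                len(contaminants), net.n_edges, part.n_modules,
                time.time() - t0)
    return {
        "name": name,
        "table": prepared,
        "contaminants": contaminants,
        "clr": clr,
        "corr": corr,
        "network": net,
        "partition": part,
        "topology": topo,
        "centralities": centr,
        "keystones": keystones,
    }


def _robustness_stage(name: str, net, cfg: RunConfig, seed: int) -> dict:
    curves = {}
    for strat in cfg.attack_strategies:
        curves[strat] = rb.attack(net, strategy=strat, reps=cfg.attack_reps,
                                  seed=seed)
    addition = rb.node_addition(net, n_max=cfg.addition_n_max,
                                reps=cfg.addition_reps, seed=seed)
    logger.info("robustness %s: %d attack strategies, %d-step growth",
                name, len(curves), cfg.addition_n_max)
    return {"attack": curves, "addition": addition}


def run_pipeline(cfg: RunConfig,
                 tables: dict[str, tuple[FeatureTable, dict[str, str]]] | None = None
                 ) -> dict:
    """Run the full comparative analysis.

    ``tables`` maps group name to (feature table, taxonomy); if omitted the
    fixtures referenced by ``cfg.fixture_dirs`` are loaded.  Returns the
    in-memory report bundle; files are written under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    cfg.to_yaml(out / "config_snapshot.yaml")

    if tables is None:
        if not cfg.fixture_dirs:
            raise ValueError("no input tables and no fixture_dirs configured")
        tables = {}
        for name, d in cfg.fixture_dirs.items():
            table, taxonomy, _ = read_fixture(d)
            tables[name] = (table, taxonomy)

    groups = {}
    for i, (name, (table, taxonomy)) in enumerate(sorted(tables.items())):
        try:
            groups[name] = _group_stage(name, table, taxonomy, cfg, cfg.seed + i)
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'group:{name}' failed: {e}") from e

    report: dict = {"config": asdict(cfg), "groups": {}}
    for name, g in groups.items():
        gdir = out / name
        gdir.mkdir(exist_ok=True)
        write_edgelist_csv(g["network"], gdir / "edges.csv")
        g["centralities"].to_csv(gdir / "centralities.tsv", sep="\t")
        g["keystones"].to_csv(gdir / "keystones.tsv", sep="\t")
        pd.DataFrame(g["corr"].rho, index=g["corr"].taxon_ids,
                     columns=g["corr"].taxon_ids).to_csv(gdir / "sparcc_rho.tsv",
                                                         sep="\t")
        report["groups"][name] = {
            "topology": vars(g["topology"]),
            "n_contaminants_removed": len(g["contaminants"]),
            "modularity_Q": g["partition"].Q,
            "n_modules": g["partition"].n_modules,
            "keystones": sorted(g["keystones"].index[g["keystones"].passes]),
        }

    names = sorted(groups)
    if len(names) >= 2:
        a, b = names[0], names[1]
        ga, gb = groups[a], groups[b]
        try:
            can = cmp.core_association_network([ga["network"], gb["network"]])
            diff = cmp.differential_network(
                ga["corr"], gb["corr"],
                ga["table"].n_samples, gb["table"].n_samples, cfg.alpha)
            jac = cmp.jaccard_centrality(ga["centralities"], gb["centralities"],
                                         cfg.jaccard_quantile)
            ari, ari_p = cmp.adjusted_rand_index(ga["partition"], gb["partition"],
                                                 seed=cfg.seed)
            equiv = cmp.module_equivalence(ga["partition"], gb["partition"])
            equiv.to_csv(out / "module_equivalence.tsv", sep="\t", index=False)
            report["comparison"] = {
                "groups": [a, b],
                "can_nodes": len(can.nodes),
                "can_edges": len(can.edges),
                "n_differential_pairs": int(len(diff.significant)),
                "jaccard": [vars(j) for j in jac],
                "ari": ari,
                "ari_p": ari_p,
            }
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'comparison' failed: {e}") from e

        try:
            rob = {n: _robustness_stage(n, groups[n]["network"], cfg, cfg.seed)
                   for n in (a, b)}
            for n in (a, b):
                for strat, curve in rob[n]["attack"].items():
                    curve.to_dataframe().to_csv(
                        out / n / f"attack_{strat}.tsv", sep="\t", index=False)
                rob[n]["addition"].to_dataframe().to_csv(
                    out / n / "addition.tsv", sep="\t", index=False)
            f80 = {n: rb.fraction_to_loss(rob[n]["attack"]["cascading"],
                                          cfg.target_loss) for n in (a, b)}
            add_cmp = rb.compare_addition(rob[a]["addition"], rob[b]["addition"],
                                          seed=cfg.seed)
            report["robustness"] = {
                "fraction_to_target_loss": f80,
                "delta_pct_points": 100.0 * (f80[a] - f80[b]),
                "addition_tests": add_cmp.to_dict(orient="records"),
            }
        except Exception as e:
            raise RuntimeError(f"pipeline stage 'robustness' failed: {e}") from e

    # focal-taxon experiments: ego sub-networks, partner overlap, knockouts
    report["focal_taxa"] = {}
    for taxon in cfg.focal_taxa:
        entry: dict = {}
        egos = {}
        for name in names:
            g = groups[name]
            if taxon not in g["network"].graph:
                continue
            egos[name] = ego_subnetwork(g["network"], taxon)
            entry[name] = {
                "n_partners": len(egos[name].partners),
                "n_positive": egos[name].n_positive,
                "n_negative": egos[name].n_negative,
            }
        if len(egos) == 2:
            ov = cmp.partner_overlap(*[egos[n] for n in names if n in egos])
            entry["partner_overlap"] = dict(zip(("only_a", "only_b", "shared"),
                                                ov.counts))
        for name in names:
            g = groups[name]
            if taxon not in g["table"].taxon_ids:
                continue
            try:
                bundle = remove_taxon_and_recompute(
                    g["table"], taxon, mode=cfg.knockout_mode,
                    threshold=cfg.edge_threshold, seed=cfg.seed,
                    baseline={k: g[k2] for k, k2 in
                              (("network", "network"), ("partition", "partition"),
                               ("topology", "topology"),
                               ("centralities", "centralities"))}
                    if cfg.knockout_mode == "delete" else None,
                )
            except Exception as e:
                raise RuntimeError(
                    f"pipeline stage 'knockout:{taxon}:{name}' failed: {e}") from e
            entry.setdefault("knockout", {})[name] = bundle["deltas"]
        report["focal_taxa"][taxon] = entry

    (out / "report.json").write_text(json.dumps(report, indent=2, default=_json_default))
    logger.info("report written to %s", out / "report.json")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def simulate_two_group_study(
    seed: int = 0,
    out_dir: str | Path | None = None,
    base_spec: GroundTruthSpec | None = None,
) -> dict[str, tuple[FeatureTable, dict[str, str]]]:
    """Generate the default two-group synthetic study.

    Group A mirrors the host whose symbiont sits inside a community module;
    group B gives the symbiont its own tiny module — the planted structural
    contrast between the two host species.  Returns ``{group: (table,
    taxonomy)}`` and optionally writes fixtures.
    """
    base = base_spec or GroundTruthSpec()
    specs = {
        "groupA": dataclasses.replace(base, symbiont_in_module=True,
                                      seed=seed),
        "groupB": dataclasses.replace(base, symbiont_in_module=False,
                                      seed=seed + 1),
    }
    tables = {}
    for name, spec in specs.items():
        truth = make_ground_truth(spec)
        table = simulate_counts(truth, spec)
        taxonomy = {t: None for t in table.taxon_ids}
        from .synth import _default_lineage

        taxonomy = {t: _default_lineage(t) for t in table.taxon_ids}
        tables[name] = (table, taxonomy)
        if out_dir is not None:
            write_fixture(table, taxonomy, None, truth,
                          Path(out_dir) / name)
    return tables
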