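"""Synthetic compositional count tables with a planted correlation structure.

The generator emulates a genus-level 16S feature table from pooled mosquito
midgut samples: ~800 taxa over two small sample groups, block-structured
basis correlations (modules), a high-connectivity keystone hub (the
*Escherichia-Shigella* analogue), a ubiquitous low-connectivity endosymbiont
(the *Wolbachia* analogue), and reagent-contaminant taxa enriched in
negative controls.  Basis abundances are multivariate log-normal and reads
are multinomial at a fixed depth — exactly the generative model under which
SparCC basis-correlation inference is well posed, which makes parameter
recovery a meaningful end-to-end check.

Ground truth (planted correlation matrix, module labels, keystone and
contaminant flags) is carried alongside the counts so every downstream stage
can be validated without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .prep import FeatureTable

__all__ = [
    "GroundTruthSpec",
    "GroundTruth",
    "make_ground_truth",
    "simulate_counts",
    "write_fixture",
    "read_fixture",
    "read_feature_table_tsv",
    "write_feature_table_tsv",
    "read_biom_json",
    "write_biom_json",
]


@dataclass
class GroundTruthSpec:
    """Parameters of the planted community structure.

    Defaults emulate the study system: 805 genus-level taxa, 13 pooled
    samples per mosquito-species group, four modules sized like the larger
    network's printed modules, a negative coupling between the two biggest
    modules, a keystone hub inside the biggest module, a symbiont with
    exactly ``symbiont_partner_count`` planted partners, and contaminants
    that show up in negative controls.
    """

    n_taxa: int = 805
    n_samples_per_group: int = 13
    n_groups: int = 2
    module_sizes: tuple[int, ...] = (208, 143, 105, 71)
    within_module_rho: float = 0.55
    between_module_rho: float = -0.55
    keystone_ids: tuple[str, ...] = ("g__Escherichia-Shigella",)
    keystone_degree_quantile: float = 1.0
    symbiont_id: str | None = "g__Wolbachia"
    symbiont_partner_count: int = 13
    symbiont_in_module: bool = False
    contaminant_ids: tuple[str, ...] = tuple(f"g__Contaminant{i:02d}" for i in range(8))
    n_negative_controls: int = 5
    basis_logmean_range: tuple[float, float] = (0.0, 6.0)
    basis_logsd: float = 1.0
    depth: int = 50_000
    seed: int = 0
    # antagonistic module pair carrying between_module_rho
    antagonist_pair: tuple[int, int] = (0, 1)
    # loading heterogeneity within a module; 0 gives exact equicorrelated blocks
    loading_spread: float = 0.05
    psd_tol: float = 0.15

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_taxa:
            raise ValueError("sum(module_sizes) exceeds n_taxa")
        for r in (self.within_module_rho, self.between_module_rho):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"correlation {r} outside [-1, 1]")
        if not 0.0 <= self.within_module_rho <= 1.0:
            raise ValueError("within_module_rho must lie in [0, 1]")
        if not -1.0 <= self.between_module_rho <= 0.0:
            raise ValueError("between_module_rho must lie in [-1, 0]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if set(self.keystone_ids) & set(self.contaminant_ids):
            raise ValueError("keystone taxa cannot also be contaminants")
        if not 0.0 < self.keystone_degree_quantile <= 1.0:
            raise ValueError("keystone_degree_quantile must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for one group's community."""

    taxon_ids: list[str]
    basis_correlation: np.ndarray
    module_labels: dict[str, int]  # -1 = background (no module)
    keystone_flags: dict[str, bool]
    contaminant_flags: dict[str, bool]
    # per-taxon log-mean of the basis abundance (drives ubiquity/abundance)
    basis_logmean: np.ndarray = field(default=None, repr=False)
    # per-taxon multiplier on the spec's basis_logsd (dominants are stabler)
    basis_logsd_scale: np.ndarray = field(default=None, repr=False)


def _taxon_names(spec: GroundTruthSpec) -> list[str]:
    special = list(spec.keystone_ids)
    if spec.symbiont_id is not None:
        special.append(spec.symbiont_id)
    special.extend(spec.contaminant_ids)
    n_filler = spec.n_taxa - len(special)
    if n_filler < 0:
        raise ValueError("n_taxa smaller than the number of named taxa")
    return special + [f"g__Taxon{i:04d}" for i in range(n_filler)]


def nearest_psd(corr: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Repair a symmetric matrix to the nearest positive semi-definite
    correlation matrix by eigenvalue clipping, then rescale to unit diagonal."""
    sym = (corr + corr.T) / 2.0
    w, v = np.linalg.eigh(sym)
    if w.min() >= -tol:
        out = sym
    else:
        w = np.clip(w, tol, None)
        out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return (out + out.T) / 2.0


#: loading ceiling for ordinary module members; the keystone hub sits above it
_MEMBER_LOADING_CAP = 0.93
_HUB_LOADING = 0.99
_SYMBIONT_LOADING = 0.95


def make_ground_truth(spec: GroundTruthSpec) -> GroundTruth:
    """Build the planted basis-correlation matrix and truth labels.

    Each module is a latent factor: member i carries a loading ``lam_i``
    centred on ``sqrt(within_module_rho)`` (spread ``loading_spread``; zero
    spread gives an exact equicorrelated block) and within-module
    correlations are ``lam_i * lam_j``.  The two biggest modules share a
    negatively correlated factor pair so their members are mutually
    antagonistic (mean correlation ``between_module_rho``), emulating
    networks whose two largest modules carry mostly negative edges between
    each other.  The keystone hub gets the top loading of its module, giving
    it a dense, strong row; the symbiont gets exactly
    ``symbiont_partner_count`` nonzero off-diagonal entries (its own small
    factor) or, alternatively, a weak loading on the third module's factor.
    The factor construction is PSD by design; any post-hoc edits (keystone
    partner subsetting) are repaired to the nearest PSD correlation matrix
    and rejected if the repair moves a planted entry beyond ``psd_tol``.
    """
    spec.validate()
    names = _taxon_names(spec)
    n = spec.n_taxa
    idx = {t: i for i, t in enumerate(names)}
    rng = np.random.default_rng(spec.seed)

    module_labels = {t: -1 for t in names}
    contaminant_set = set(spec.contaminant_ids)
    # eligible members for modules: everything except contaminants and symbiont
    eligible = [t for t in names if t not in contaminant_set and t != spec.symbiont_id]
    # keystones go first so they land in module 0 (the biggest)
    eligible = list(spec.keystone_ids) + [t for t in eligible if t not in spec.keystone_ids]
    pos = 0
    modules: list[list[str]] = []
    for m, size in enumerate(spec.module_sizes):
        members = eligible[pos:pos + size]
        if len(members) < size:
            raise ValueError("not enough non-contaminant taxa to fill module_sizes")
        for t in members:
            module_labels[t] = m
        modules.append(members)
        pos += size

    n_factors = len(modules) + 1  # last factor reserved for the symbiont clique
    lam = np.zeros(n)
    factor_of = np.full(n, -1)
    base = float(np.sqrt(spec.within_module_rho))
    for m, members in enumerate(modules):
        for t in members:
            i = idx[t]
            factor_of[i] = m
            if spec.loading_spread == 0.0 or base == 0.0:
                lam[i] = base
            else:
                lam[i] = min(
                    _MEMBER_LOADING_CAP,
                    rng.uniform(base - spec.loading_spread,
                                base + spec.loading_spread),
                )
    for k in spec.keystone_ids:
        if module_labels[k] >= 0 and spec.loading_spread > 0.0:
            lam[idx[k]] = _HUB_LOADING

    # symbiont wiring: own tiny factor (exact partner count) or a weak
    # loading on the third module's factor (partners emerge from overlap)
    symbiont_partners: list[str] = []
    if spec.symbiont_id is not None and spec.symbiont_partner_count > 0:
        s = idx[spec.symbiont_id]
        if spec.symbiont_in_module and len(modules) > 2:
            factor_of[s] = 2
            lam[s] = 0.8 * base  # weak coupling: only top members cross threshold
            module_labels[spec.symbiont_id] = 2
        else:
            pool = [t for t in names if module_labels[t] == -1
                    and t not in contaminant_set and t != spec.symbiont_id]
            symbiont_partners = pool[: spec.symbiont_partner_count]
            if len(symbiont_partners) < spec.symbiont_partner_count:
                raise ValueError("not enough background taxa for symbiont partners")
            factor_of[s] = n_factors - 1
            lam[s] = _SYMBIONT_LOADING
            m_next = len(spec.module_sizes)
            module_labels[spec.symbiont_id] = m_next
            for t in symbiont_partners:
                i = idx[t]
                factor_of[i] = n_factors - 1
                lam[i] = (base if spec.loading_spread == 0.0 and base > 0
                          else rng.uniform(0.85, _MEMBER_LOADING_CAP))
                module_labels[t] = m_next

    # factor correlation: antagonist pair negative, everything else independent
    phi = np.eye(n_factors)
    a, b = spec.antagonist_pair
    if spec.within_module_rho > 0 and len(modules) > max(a, b):
        phi_ab = float(np.clip(spec.between_module_rho / spec.within_module_rho,
                               -1.0, 0.0))
        phi[a, b] = phi[b, a] = phi_ab

    assigned = factor_of >= 0
    corr = np.eye(n)
    if assigned.any():
        ii = np.where(assigned)[0]
        sub = np.outer(lam[ii], lam[ii]) * phi[np.ix_(factor_of[ii], factor_of[ii])]
        corr[np.ix_(ii, ii)] = sub
        np.fill_diagonal(corr, 1.0)

    # keystone partner subsetting: hub entries outside the chosen partner
    # fraction fall back to an ordinary member loading
    edited = False
    for k in spec.keystone_ids:
        m = module_labels[k]
        if m < 0 or spec.keystone_degree_quantile >= 1.0:
            continue
        partners = [t for t in modules[m] if t != k]
        n_part = int(np.ceil(spec.keystone_degree_quantile * len(partners)))
        for t in partners[n_part:]:
            val = base * lam[idx[t]]
            corr[idx[k], idx[t]] = corr[idx[t], idx[k]] = val
            edited = True

    if edited:
        repaired = nearest_psd(corr)
        planted = np.abs(corr - np.eye(n)) > 0
        dev = np.abs(repaired - corr)[planted].max() if planted.any() else 0.0
        if dev > spec.psd_tol:
            raise ValueError(
                f"planted correlation structure is not repairable to PSD within "
                f"tolerance (max planted-entry change {dev:.3f} > {spec.psd_tol})"
            )
        corr = repaired

    # basis log-means: the community spans the full range; keystone and
    # symbiont sit above it (dominant, ubiquitous taxa, as in real midgut
    # tables)
    lo, hi = spec.basis_logmean_range
    logmean = rng.uniform(lo, hi, size=n)
    for k in spec.keystone_ids:
        logmean[idx[k]] = hi + 1.5
    if spec.symbiont_id is not None:
        logmean[idx[spec.symbiont_id]] = hi + 1.0

    return GroundTruth(
        taxon_ids=names,
        basis_correlation=corr,
        module_labels=module_labels,
        keystone_flags={t: t in spec.keystone_ids for t in names},
        contaminant_flags={t: t in contaminant_set for t in names},
        basis_logmean=logmean,
    )


def simulate_counts(
    truth: GroundTruth, spec: GroundTruthSpec, seed: int | None = None
) -> FeatureTable:
    """Draw one group's count table (plus negative controls) from the truth.

    Per real sample: basis abundances are multivariate log-normal with the
    planted correlation (on the log scale, sd ``basis_logsd``), closed to
    fractions and read off as one multinomial draw at ``spec.depth``.
    Contaminant taxa are forced present in >= 80% of negative controls and
    <= 20% of real samples; controls are low-biomass (10% of the depth) and
    dominated by contaminants.
    """
    if spec.depth < 100:
        raise ValueError("depth must be at least 100 reads per sample")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = len(truth.taxon_ids)
    n_real = spec.n_samples_per_group
    n_ctrl = spec.n_negative_controls
    contam = np.array([truth.contaminant_flags[t] for t in truth.taxon_ids])

    sd = spec.basis_logsd * (
        truth.basis_logsd_scale if truth.basis_logsd_scale is not None
        else np.ones(n)
    )
    cov = np.outer(sd, sd) * truth.basis_correlation
    # tiny jitter keeps Cholesky stable after eigen-clipping
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(n))
    z = truth.basis_logmean + (chol @ rng.standard_normal((n, n_real))).T  # samples x taxa
    basis = np.exp(z)

    # contaminants: present in a fixed <=20% subset of real samples, tiny level
    n_present_real = int(np.floor(0.15 * n_real))
    for j in np.where(contam)[0]:
        present = rng.choice(n_real, size=n_present_real, replace=False)
        mask = np.zeros(n_real, dtype=bool)
        mask[present] = True
        basis[~mask, j] = 0.0
        basis[mask, j] *= 0.05

    counts = np.zeros((n_real + n_ctrl, n), dtype=np.int64)
    for s in range(n_real):
        frac = basis[s] / basis[s].sum()
        counts[s] = rng.multinomial(spec.depth, frac)

    # negative controls: contaminants high, cross-talk from real community low
    ctrl_depth = max(100, spec.depth // 10)
    lo, hi = spec.basis_logmean_range
    n_present_ctrl = int(np.ceil(0.9 * n_ctrl)) if n_ctrl else 0
    contam_present = np.zeros((n_ctrl, n), dtype=bool)
    for j in np.where(contam)[0]:
        present = rng.choice(n_ctrl, size=n_present_ctrl, replace=False)
        contam_present[present, j] = True
    for s in range(n_ctrl):
        b = np.zeros(n)
        cross = rng.random(n) < 0.05  # sporadic low-level carry-over
        b[cross] = np.exp(rng.uniform(lo - 2, lo, size=int(cross.sum())))
        jj = contam_present[s]
        b[jj] = np.exp(rng.uniform(hi, hi + 2, size=int(jj.sum())))
        if b.sum() == 0:
            b[rng.integers(n)] = 1.0
        counts[n_real + s] = rng.multinomial(ctrl_depth, b / b.sum())

    sample_ids = [f"S{i + 1:02d}" for i in range(n_real)] + [
        f"NC{i + 1:02d}" for i in range(n_ctrl)
    ]
    is_control = np.array([False] * n_real + [True] * n_ctrl)
    return FeatureTable(
        taxon_ids=list(truth.taxon_ids),
        sample_ids=sample_ids,
        counts=counts.T,
        is_control=is_control,
    )


# ---------------------------------------------------------------------------
# fixture I/O (TSV, BIOM 1.0 JSON, taxonomy, metadata, ground truth)
# ---------------------------------------------------------------------------

def write_feature_table_tsv(table: FeatureTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def read_feature_table_tsv(
    path: str | Path, metadata: dict[str, bool] | None = None
) -> FeatureTable:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    is_control = None
    if metadata is not None:
        is_control = np.array([bool(metadata.get(s, False)) for s in df.columns])
    return FeatureTable(
        taxon_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
        counts=df.to_numpy(dtype=np.int64),
        is_control=is_control,
    )


def write_biom_json(table: FeatureTable, path: str | Path) -> None:
    """Write a BIOM 1.0 dense JSON table (OTU table, matrix_type 'dense')."""
    obj = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "coocnet",
        "date": "",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [table.n_taxa, table.n_samples],
        "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
        "columns": [
            {"id": s, "metadata": {"is_negative_control": int(c)}}
            for s, c in zip(table.sample_ids, table.is_control)
        ],
        "data": table.counts.astype(int).tolist(),
    }
    Path(path).write_text(json.dumps(obj))


def read_biom_json(path: str | Path) -> FeatureTable:
    obj = json.loads(Path(path).read_text())
    counts = np.asarray(obj["data"], dtype=np.int64)
    if obj.get("matrix_type") == "sparse":
        dense = np.zeros(obj["shape"], dtype=np.int64)
        for r, c, v in obj["data"]:
            dense[int(r), int(c)] = int(v)
        counts = dense
    cols = obj["columns"]
    is_control = np.array(
        [bool((c.get("metadata") or {}).get("is_negative_control", 0)) for c in cols]
    )
    return FeatureTable(
        taxon_ids=[r["id"] for r in obj["rows"]],
        sample_ids=[c["id"] for c in cols],
        counts=counts,
        is_control=is_control,
    )


def _default_lineage(taxon: str) -> str:
    genus = taxon[3:] if taxon.startswith("g__") else taxon
    return (
        f"d__Bacteria;p__Synthetica;c__Synthetica;o__Synthetica;"
        f"f__Synthetica;g__{genus}"
    )


def write_fixture(
    table: FeatureTable,
    taxonomy: dict[str, str],
    metadata: "pd.DataFrame | None",
    truth: GroundTruth | None,
    out_dir: str | Path,
    include_matrix: bool = False,
) -> dict[str, Path]:
    """Write the fixture file set: counts TSV, BIOM JSON, taxonomy TSV,
    metadata TSV and ground-truth JSON.  Round-trip reads reproduce the
    integer matrix exactly."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    try:
        paths["table_tsv"] = out / "feature_table.tsv"
        write_feature_table_tsv(table, paths["table_tsv"])
        paths["table_biom"] = out / "feature_table.biom.json"
        write_biom_json(table, paths["table_biom"])

        paths["taxonomy"] = out / "taxonomy.tsv"
        tax = pd.DataFrame(
            {"taxon_id": table.taxon_ids,
             "lineage": [taxonomy.get(t, _default_lineage(t)) for t in table.taxon_ids]}
        )
        tax.to_csv(paths["taxonomy"], sep="\t", index=False)

        paths["metadata"] = out / "metadata.tsv"
        if metadata is None:
            metadata = pd.DataFrame(
                {"sample_id": table.sample_ids,
                 "is_negative_control": table.is_control.astype(int)}
            )
        metadata.to_csv(paths["metadata"], sep="\t", index=False)

        if truth is not None:
            paths["truth"] = out / "ground_truth.json"
            obj = {
                "taxon_ids": truth.taxon_ids,
                "module_labels": truth.module_labels,
                "keystone_flags": truth.keystone_flags,
                "contaminant_flags": truth.contaminant_flags,
            }
            if include_matrix:
                obj["basis_correlation"] = truth.basis_correlation.tolist()
            paths["truth"].write_text(json.dumps(obj))
    except OSError as e:
        raise OSError(f"failed writing fixture under {out}: {e}") from e
    return paths


def read_fixture(fixture_dir: str | Path) -> tuple[FeatureTable, dict[str, str], GroundTruth | None]:
    import pandas as pd

    d = Path(fixture_dir)
    meta = pd.read_csv(d / "metadata.tsv", sep="\t")
    roles = dict(zip(meta["sample_id"].astype(str), meta["is_negative_control"].astype(bool)))
    table = read_feature_table_tsv(d / "feature_table.tsv", metadata=roles)
    tax_df = pd.read_csv(d / "taxonomy.tsv", sep="\t")
    taxonomy = dict(zip(tax_df["taxon_id"].astype(str), tax_df["lineage"].astype(str)))
    truth = None
    tpath = d / "ground_truth.json"
    if tpath.exists():
        obj = json.loads(tpath.read_text())
        truth = GroundTruth(
            taxon_ids=obj["taxon_ids"],
            basis_correlation=np.asarray(obj["basis_correlation"])
            if "basis_correlation" in obj else None,
            module_labels={k: int(v) for k, v in obj["module_labels"].items()},
            keystone_flags={k: bool(v) for k, v in obj["keystone_flags"].items()},
            contaminant_flags={k: bool(v) for k, v in obj["contaminant_flags"].items()},
        )
    return table, taxonomy, truth
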