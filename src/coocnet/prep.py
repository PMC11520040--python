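"""Count-table preparation: contaminant screening, genus collapse, rare-taxon
filtering and the centered log-ratio transform.

The container used throughout the package is :class:`FeatureTable`, a
taxa-by-samples matrix of non-negative integer read counts in which every
sample is labelled either ``real`` or ``negative_control``.  The preparation
stages mirror standard 16S amplicon practice: negative-control-based
contaminant identification (prevalence test), collapse of features to the
genus rank, removal of rare taxa, and a clr transform that places the
compositional counts in an unconstrained Euclidean space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FeatureTable",
    "ClrMatrix",
    "identify_contaminants",
    "collapse_to_genus",
    "filter_rare",
    "clr_transform",
]

RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__")


@dataclass
class FeatureTable:
    """Taxa x samples count table with sample roles.

    Parameters
    ----------
    taxon_ids
        Row identifiers (unique).
    sample_ids
        Column identifiers (unique).
    counts
        Non-negative integer matrix, shape ``(n_taxa, n_samples)``.
    is_control
        Boolean vector over samples; True marks a negative control.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    is_control: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValueError("duplicate taxon identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.is_control is None:
            self.is_control = np.zeros(len(self.sample_ids), dtype=bool)
        self.is_control = np.asarray(self.is_control, dtype=bool)
        if self.is_control.all():
            raise ValueError("feature table must contain at least one real sample")

    # -- convenience -------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def real_samples(self) -> "FeatureTable":
        """Sub-table holding only the non-control samples."""
        keep = ~self.is_control
        return FeatureTable(
            taxon_ids=list(self.taxon_ids),
            sample_ids=[s for s, k in zip(self.sample_ids, keep) if k],
            counts=self.counts[:, keep],
            is_control=np.zeros(int(keep.sum()), dtype=bool),
        )

    def drop_taxa(self, taxa: list[str]) -> "FeatureTable":
        drop = set(taxa)
        keep = [i for i, t in enumerate(self.taxon_ids) if t not in drop]
        return FeatureTable(
            taxon_ids=[self.taxon_ids[i] for i in keep],
            sample_ids=list(self.sample_ids),
            counts=self.counts[keep, :],
            is_control=self.is_control.copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)


@dataclass
class ClrMatrix:
    """Centered log-ratio abundances on the same axes as a FeatureTable."""

    taxon_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    pseudocount: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)

    def mean_clr(self) -> pd.Series:
        """Per-taxon mean clr abundance across samples."""
        return pd.Series(self.values.mean(axis=1), index=self.taxon_ids)


def identify_contaminants(table: FeatureTable, score_threshold: float = 0.1) -> list[str]:
    """Flag likely reagent contaminants by the prevalence method.

    For each taxon a 2x2 presence/absence table (negative controls vs real
    samples) is tested one-sidedly (Fisher exact) for *higher* prevalence in
    the controls; taxa with p < ``score_threshold`` are returned.  The caller
    is expected to drop the returned taxa before any downstream stage.
    """
    n_ctrl = int(table.is_control.sum())
    if n_ctrl == 0:
        raise ValueError(
            "no negative controls present; skip the contaminant screening stage"
        )
    present = table.counts > 0
    ctrl = table.is_control
    n_real = table.n_samples - n_ctrl
    flagged = []
    for i, taxon in enumerate(table.taxon_ids):
        k_ctrl = int(present[i, ctrl].sum())
        k_real = int(present[i, ~ctrl].sum())
        _, p = stats.fisher_exact(
            [[k_ctrl, n_ctrl - k_ctrl], [k_real, n_real - k_real]],
            alternative="greater",
        )
        if p < score_threshold:
            flagged.append(taxon)
    return flagged


def _genus_collapse_key(lineage: str) -> str:
    """Collapse key for a SILVA-style ranked lineage string.

    Resolved genera collapse on the lineage truncated at the genus rank;
    unresolved ones keep the deepest resolved rank, marked ``unresolved|`` so
    they never merge with a resolved genus of the same name.
    """
    parts = [p.strip() for p in lineage.split(";")]
    ranks: dict[str, str] = {}
    for part in parts:
        for pref in RANK_PREFIXES:
            if part.startswith(pref):
                ranks[pref] = part[len(pref):].strip()
                break
    if not ranks or all(v == "" for v in ranks.values()):
        raise ValueError(f"malformed lineage: {lineage!r}")
    if ranks.get("g__", ""):
        upto = RANK_PREFIXES.index("g__") + 1
        return ";".join(f"{p}{ranks.get(p, '')}" for p in RANK_PREFIXES[:upto])
    # deepest resolved rank
    for pref in reversed(RANK_PREFIXES):
        if ranks.get(pref, ""):
            return f"unresolved|{pref}{ranks[pref]}"
    raise ValueError(f"malformed lineage: {lineage!r}")


def collapse_to_genus(table: FeatureTable, taxonomy: dict[str, str]) -> FeatureTable:
    """Sum counts over features sharing a genus-level lineage.

    ``taxonomy`` maps each taxon id to a ranked lineage string
    (``d__...;p__...;...;g__...``).  Features whose lineage cannot be parsed
    are dropped with a warning; total reads of parseable rows are conserved
    exactly.
    """
    keys: list[str | None] = []
    for t in table.taxon_ids:
        if t not in taxonomy:
            raise ValueError(f"taxon {t!r} missing from taxonomy")
        try:
            keys.append(_genus_collapse_key(taxonomy[t]))
        except ValueError as e:
            warnings.warn(f"dropping feature {t!r}: {e}")
            keys.append(None)
    order: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for i, key in enumerate(keys):
        if key is None:
            continue
        if key not in rows:
            rows[key] = table.counts[i].copy()
            order.append(key)
        else:
            rows[key] = rows[key] + table.counts[i]
    # readable labels: the genus rank alone, disambiguated by family only
    # when the same genus string occurs under different lineages
    def short_label(key: str) -> str:
        if key.startswith("unresolved|"):
            return key
        parts = key.split(";")
        return parts[-1]

    label_counts: dict[str, int] = {}
    for k in order:
        label_counts[short_label(k)] = label_counts.get(short_label(k), 0) + 1

    def label(key: str) -> str:
        s = short_label(key)
        if label_counts[s] > 1 and not key.startswith("unresolved|"):
            family = key.split(";")[-2]
            return f"{family}|{s}"
        return s

    return FeatureTable(
        taxon_ids=[label(k) for k in order],
        sample_ids=list(table.sample_ids),
        counts=np.vstack([rows[k] for k in order]),
        is_control=table.is_control.copy(),
    )


def filter_rare(
    table: FeatureTable, min_total_reads: int = 10, min_prevalence: int = 3
) -> FeatureTable:
    """Drop taxa with fewer than ``min_total_reads`` total reads or present in
    fewer than ``min_prevalence`` samples.  Samples are unchanged."""
    total = table.counts.sum(axis=1)
    prevalence = (table.counts > 0).sum(axis=1)
    keep = (total >= min_total_reads) & (prevalence >= min_prevalence)
    if not keep.any():
        raise ValueError("rare-taxon filter removed every taxon")
    return FeatureTable(
        taxon_ids=[t for t, k in zip(table.taxon_ids, keep) if k],
        sample_ids=list(table.sample_ids),
        counts=table.counts[keep, :],
        is_control=table.is_control.copy(),
    )


def clr_transform(table: FeatureTable, pseudocount: float = 0.5) -> ClrMatrix:
    """Centered log-ratio transform, per sample.

    ``clr(x_i) = ln(x_i + pc) - mean_j ln(x_j + pc)`` so that each sample's
    clr values sum to zero.  A positive pseudocount is required whenever the
    table contains zeros.
    """
    x = table.counts.astype(float) + pseudocount
    if np.any(x <= 0):
        raise ValueError("non-positive values after pseudocount; use pseudocount > 0")
    logx = np.log(x)
    vals = logx - logx.mean(axis=0, keepdims=True)
    return ClrMatrix(
        taxon_ids=list(table.taxon_ids),
        sample_ids=list(table.sample_ids),
        values=vals,
        pseudocount=pseudocount,
    )
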