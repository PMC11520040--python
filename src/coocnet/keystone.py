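"""Keystone taxon identification.

A taxon is called a keystone when it jointly satisfies three criteria:
(i) ubiquitous presence — nonzero counts in every (real) sample of the
group; (ii) high eigenvector centrality (>= ``ev_threshold``, default 0.75,
on the max-1 scale); (iii) high relative abundance — its mean clr value
across samples exceeds the grand mean of all taxa's mean clr values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .prep import ClrMatrix, FeatureTable

__all__ = ["identify_keystones"]


def identify_keystones(
    table: FeatureTable,
    clr: ClrMatrix,
    centralities: pd.DataFrame,
    ev_threshold: float = 0.75,
) -> pd.DataFrame:
    """Per-taxon keystone report.

    Returns a DataFrame indexed by taxon with columns ``is_ubiquitous``,
    ``eigenvector``, ``mean_clr``, ``passes``; the threshold used is stored
    in ``df.attrs``.  All three inputs must cover every taxon of ``table``
    (only real samples are consulted for ubiquity and abundance).
    """
    real = table.real_samples()
    taxa = real.taxon_ids
    missing = [t for t in taxa if t not in clr.taxon_ids]
    if missing:
        raise ValueError(f"taxa missing from clr matrix: {missing[:5]}")
    missing = [t for t in taxa if t not in centralities.index]
    if missing:
        raise ValueError(f"taxa missing from centrality table: {missing[:5]}")

    ubiquitous = pd.Series((real.counts > 0).all(axis=1), index=taxa)
    mean_clr = clr.mean_clr().reindex(taxa)
    grand_mean = float(mean_clr.mean())
    ev = centralities["eigenvector"].reindex(taxa)

    passes = ubiquitous & (ev >= ev_threshold) & (mean_clr > grand_mean)
    report = pd.DataFrame(
        {
            "is_ubiquitous": ubiquitous,
            "eigenvector": ev,
            "mean_clr": mean_clr,
            "passes": passes,
        },
        index=pd.Index(taxa, name="taxon_id"),
    )
    report.attrs["ev_threshold"] = ev_threshold
    report.attrs["grand_mean_clr"] = grand_mean
    return report
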