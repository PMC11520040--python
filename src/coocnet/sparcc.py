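"""SparCC basis-correlation inference for compositional count data.

Sequencing counts only carry relative information; naive Pearson
correlations of fractions are distorted by the closure.  SparCC inverts the
log-ratio variance matrix

    t_ij = Var_samples[ ln(x_i / x_j) ]

under a sparsity assumption: for most pairs the basis correlation is near
zero, so ``t_ij ~ w_i + w_j`` where ``w_i`` is the (unobserved) variance of
taxon i's log basis abundance.  Summing over j gives the linear system

    sum_j t_ij = (D - 1) w_i + sum_{j != i} w_j

solved for the basis variances ``w``, from which

    rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).

Strongly correlated pairs violate the sparsity assumption; an exclusion
loop iteratively removes the most-correlated pair from the system and
re-solves.  Sampling noise in the counts is integrated out by resampling
fractions from a Dirichlet posterior over several inner iterations and
taking the elementwise median.  Edge-level significance comes from a
permutation bootstrap (per-taxon shuffles across samples).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .prep import FeatureTable

__all__ = [
    "CorrelationResult",
    "logratio_variance",
    "estimate_basis_correlations",
    "bootstrap_pvalues",
]

_OMEGA_FLOOR = 1e-6


@dataclass
class CorrelationResult:
    """Basis correlations with the intermediate SparCC quantities."""

    taxon_ids: list[str]
    rho: np.ndarray              # basis correlations, symmetric, unit diagonal
    logratio_var: np.ndarray     # t_ij from the last inner iteration
    basis_var: np.ndarray        # w_i from the last inner iteration
    n_inner: int
    excluded_pairs: list[tuple[int, int]]
    seed: int
    pvals: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = self.rho.shape[0]
        if self.rho.shape != (d, d) or d != len(self.taxon_ids):
            raise ValueError("rho shape inconsistent with taxon_ids")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.rho, index=self.taxon_ids, columns=self.taxon_ids)


def logratio_variance(fractions: np.ndarray) -> np.ndarray:
    """Variation matrix t_ij = Var over samples of ln(x_i/x_j).

    ``fractions`` is samples x taxa, strictly positive.  Computed through the
    log-covariance identity ``t_ij = C_ii + C_jj - 2 C_ij``.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.shape[0] < 3:
        raise ValueError("log-ratio variance needs at least 3 samples")
    if np.any(fractions <= 0):
        raise ValueError("fractions must be strictly positive")
    logx = np.log(fractions)
    cov = np.cov(logx, rowvar=False)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = np.maximum((t + t.T) / 2.0, 0.0)
    np.fill_diagonal(t, 0.0)
    return t


def _solve_basis_variances(
    t: np.ndarray, n_exclude: int, exclude_threshold: float
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int]]]:
    """One SparCC pass: solve for w, iteratively excluding strong pairs.

    A taxon already excluded in D-3 pairs is saturated: excluding more of
    its pairs would make the linear system singular, so its remaining pairs
    are left in place (the reference implementation's component-exclusion
    guard).
    """
    d = t.shape[0]
    # M w = t 1 with M_ii = D-1, M_ij = 1; exclusions knock entries out
    m = np.ones((d, d)) + np.eye(d) * (d - 2)
    t_work = t.copy()
    excluded: list[tuple[int, int]] = []
    n_excl_of = np.zeros(d, dtype=int)

    def solve() -> np.ndarray:
        try:
            w = np.linalg.solve(m, t_work.sum(axis=1))
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(
                f"singular basis-variance system (D={d}): {e}"
            ) from e
        if np.any(w <= 0):
            warnings.warn("negative basis variance solved; flooring to small positive")
            w = np.where(w <= 0, _OMEGA_FLOOR, w)
        return w

    def rho_from(w: np.ndarray) -> np.ndarray:
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        np.fill_diagonal(rho, 1.0)
        return np.clip(rho, -1.0, 1.0)

    w = solve()
    rho = rho_from(w)
    for _ in range(n_exclude):
        masked = np.abs(rho).copy()
        np.fill_diagonal(masked, 0.0)
        for i, j in excluded:
            masked[i, j] = masked[j, i] = 0.0
        saturated = n_excl_of >= d - 3
        masked[saturated, :] = 0.0
        masked[:, saturated] = 0.0
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclude_threshold:
            break
        excluded.append((min(i, j), max(i, j)))
        n_excl_of[i] += 1
        n_excl_of[j] += 1
        m[i, j] = m[j, i] = 0.0
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        t_work[i, j] = t_work[j, i] = 0.0
        w = solve()
        rho = rho_from(w)
    return w, rho, excluded


def _dirichlet_fractions(counts: np.ndarray, pseudocount: float, rng) -> np.ndarray:
    """Posterior draw of per-sample fractions, counts samples x taxa."""
    g = rng.gamma(counts + pseudocount)
    return g / g.sum(axis=1, keepdims=True)


def estimate_basis_correlations(
    table: FeatureTable | np.ndarray,
    n_inner: int = 20,
    n_exclude: int = 10,
    exclude_threshold: float = 0.1,
    pseudocount: float = 0.5,
    seed: int = 0,
) -> CorrelationResult:
    """Estimate the taxa x taxa basis-correlation matrix from counts.

    ``table`` is a FeatureTable (real samples only are used) or a raw
    taxa x samples count array.  Per inner iteration, fractions are drawn
    from the Dirichlet posterior (counts + pseudocount) and the SparCC system
    is solved with pair exclusion; the final estimate is the elementwise
    median over inner iterations, clamped to [-1, 1].
    """
    if isinstance(table, FeatureTable):
        taxon_ids = list(table.taxon_ids)
        counts = table.real_samples().counts.T.astype(float)  # samples x taxa
    else:
        counts = np.asarray(table, dtype=float).T
        taxon_ids = [f"T{i}" for i in range(counts.shape[1])]
    n_samples, d = counts.shape
    if d < 4:
        raise ValueError("SparCC needs at least 4 taxa")
    if n_samples < 3:
        raise ValueError("SparCC needs at least 3 samples")

    rng = np.random.default_rng(seed)
    rhos = np.empty((n_inner, d, d))
    last = None
    # Dirichlet draws are made in canonical (sorted-id) taxon order so that
    # relabelling taxa permutes the estimate consistently
    canon = np.argsort(np.argsort(taxon_ids))
    for it in range(n_inner):
        frac = _dirichlet_fractions(counts[:, np.argsort(taxon_ids)],
                                    pseudocount, rng)[:, canon]
        t = logratio_variance(frac)
        w, rho, excluded = _solve_basis_variances(t, n_exclude, exclude_threshold)
        rhos[it] = rho
        last = (t, w, excluded)
    rho_med = np.clip(np.median(rhos, axis=0), -1.0, 1.0)
    rho_med = (rho_med + rho_med.T) / 2.0
    np.fill_diagonal(rho_med, 1.0)
    t, w, excluded = last
    return CorrelationResult(
        taxon_ids=taxon_ids,
        rho=rho_med,
        logratio_var=t,
        basis_var=w,
        n_inner=n_inner,
        excluded_pairs=excluded,
        seed=seed,
    )


def bootstrap_pvalues(
    table: FeatureTable | np.ndarray,
    observed: CorrelationResult,
    n_boot: int = 100,
    n_inner: int = 5,
    n_exclude: int = 10,
    exclude_threshold: float = 0.1,
    pseudocount: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Permutation pseudo p-values for each correlation.

    Each bootstrap permutes every taxon's counts across samples
    independently (destroying all between-taxon dependence), re-estimates
    the correlation matrix, and counts how often ``|rho_boot| >= |rho_hat|``;
    +1 smoothing keeps p in (0, 1].
    """
    if n_boot < 10:
        warnings.warn("n_boot < 10 gives very coarse p-values")
    if isinstance(table, FeatureTable):
        counts = table.real_samples().counts.T.astype(float)
    else:
        counts = np.asarray(table, dtype=float).T
    n_samples, d = counts.shape
    rng = np.random.default_rng(seed)
    abs_obs = np.abs(observed.rho)
    exceed = np.zeros((d, d))
    for b in range(n_boot):
        perm = np.empty_like(counts)
        for j in range(d):
            perm[:, j] = counts[rng.permutation(n_samples), j]
        res = estimate_basis_correlations(
            perm.T, n_inner=n_inner, n_exclude=n_exclude,
            exclude_threshold=exclude_threshold, pseudocount=pseudocount,
            seed=int(rng.integers(2**31)),
        )
        exceed += np.abs(res.rho) >= abs_obs
    pvals = (exceed + 1.0) / (n_boot + 1.0)
    np.fill_diagonal(pvals, 1.0 / (n_boot + 1.0))
    return pvals
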