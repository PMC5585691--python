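"""Symmetric cooccurrence matrices: Spearman and SparCC.

Two flavors are used downstream: *temporal* (computed over daily fecal
samples — which taxa rise and fall together in time) and *spatial*
(computed over the 7 per-site mean profiles of the biopsy samples — which
taxa reside in the same GI locations).

SparCC estimates correlations between unobserved basis abundances from the
log-ratio variances of compositional count data, under a sparsity
assumption: t_ij = var(log(x_i/x_j)) = ω_i² + ω_j² − 2ρ_ij ω_i ω_j, and
with most ρ ≈ 0 the basis variances ω² solve a linear system in the row
sums of t. Strongly correlated pairs are iteratively excluded from that
system; uncertainty in the fractions is integrated over by Dirichlet
resampling, with a median aggregate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .io import SITES, CountTable, SampleMetadata


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise association matrix with unit diagonal."""

    taxa_ids: list[str]
    matrix: np.ndarray
    method: str  # spearman | sparcc
    flavor: str = "temporal"  # temporal | spatial

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("correlation matrix shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("correlation matrix is not symmetric")
        if np.nanmax(np.abs(self.matrix)) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return len(self.taxa_ids)


def spearman_matrix(
    table: CountTable, flavor: str = "temporal"
) -> CorrelationMatrix:
    """All-pairs Spearman rank correlation of relative abundance profiles.

    Ties get average ranks. A constant taxon has undefined rank correlation;
    its off-diagonal entries are set to 0 (degenerate) rather than NaN.
    """
    if table.n_samples < 3:
        raise ValueError("need at least 3 observations per taxon")
    rel = table.relative_abundance()
    ranks = np.apply_along_axis(rankdata, 1, rel)  # average ranks for ties
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    rho = np.nan_to_num(np.asarray(rho, dtype=float))
    constant = np.ptp(rel, axis=1) == 0
    rho[constant, :] = 0.0
    rho[:, constant] = 0.0
    np.fill_diagonal(rho, 1.0)
    rho = np.clip((rho + rho.T) / 2, -1.0, 1.0)
    return CorrelationMatrix(list(table.taxa_ids), rho, "spearman", flavor)


def _basis_correlations(
    logf: np.ndarray, n_outer: int, exclusion_threshold: float
) -> np.ndarray:
    """One SparCC estimate from log-fraction data (taxa × samples)."""
    n = logf.shape[0]
    # variation matrix t_ij = var(log(x_i/x_j))
    var_t = np.var(logf[:, None, :] - logf[None, :, :], axis=2, ddof=1)
    active = ~np.eye(n, dtype=bool)
    rho = None
    for _ in range(n_outer + 1):
        deg = active.sum(axis=1)
        m = active.astype(float)
        np.fill_diagonal(m, deg)
        t_row = (var_t * active).sum(axis=1)
        try:
            omega2 = np.linalg.solve(m, t_row)
        except np.linalg.LinAlgError:
            warnings.warn("basis-variance system singular; stopping exclusions")
            break
        omega2 = np.clip(omega2, 1e-12, None)
        omega = np.sqrt(omega2)
        new_rho = (omega2[:, None] + omega2[None, :] - var_t) / (
            2 * np.outer(omega, omega)
        )
        new_rho = np.clip(new_rho, -1.0, 1.0)
        np.fill_diagonal(new_rho, 1.0)
        rho = new_rho
        # exclude the strongest remaining off-diagonal pair above threshold
        cand = np.abs(rho) * active
        np.fill_diagonal(cand, 0.0)
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        if active[i].sum() <= 2 or active[j].sum() <= 2:
            break  # keep the system well determined
        active[i, j] = active[j, i] = False
    return rho


def sparcc_matrix(
    raw_counts: CountTable,
    n_outer: int = 10,
    exclusion_threshold: float = 0.1,
    n_inner: int = 20,
    seed: int | None = None,
    flavor: str = "temporal",
) -> CorrelationMatrix:
    """SparCC basis correlations from a raw count table.

    Each of `n_inner` iterations draws per-sample fractions from a
    Dirichlet(counts + 1) posterior, estimates basis correlations with up to
    `n_outer` strong-pair exclusion rounds, and the final matrix is the
    entrywise median, symmetrized and clipped to [−1, 1].
    """
    if raw_counts.n_taxa < 4:
        raise ValueError("SparCC needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_inner):
        fracs = np.column_stack(
            [rng.dirichlet(raw_counts.values[:, j] + 1) for j in range(raw_counts.n_samples)]
        )
        estimates.append(
            _basis_correlations(np.log(fracs), n_outer, exclusion_threshold)
        )
    med = np.median(np.stack(estimates), axis=0)
    med = np.clip((med + med.T) / 2, -1.0, 1.0)
    np.fill_diagonal(med, 1.0)
    return CorrelationMatrix(list(raw_counts.taxa_ids), med, "sparcc", flavor)


def spatial_profile_table(
    biopsy: CountTable, metadata: SampleMetadata
) -> CountTable:
    """Per-site mean relative abundance per OTU, columns ordered TI→R.

    With triplicate biopsies this is the mean of three replicates; if a
    replicate is missing the mean is over those available (with a warning).
    """
    layout = metadata.biopsy_layout()
    sample_ids = [s for s in layout["sample_id"] if s in set(biopsy.sample_ids)]
    sub = biopsy.select_samples(sample_ids)
    rel = sub.relative_abundance()
    cols = []
    for site in SITES:
        idx = [k for k, s in enumerate(sample_ids) if layout.at[s, "site"] == site]
        if not idx:
            raise ValueError(f"no biopsy samples for site {site}")
        if len(idx) < 3:
            warnings.warn(f"site {site} has only {len(idx)} replicates")
        cols.append(rel[:, idx].mean(axis=1))
    return CountTable(np.column_stack(cols), list(sub.taxa_ids), list(SITES))
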