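"""Alpha diversity, Bray-Curtis distances, NMDS ordination and ANOSIM.

Shannon entropy is computed in nats so that Pielou's evenness H/ln(S) is
bounded by 1. ANOSIM follows Clarke's rank-based statistic
R = (r̄_between − r̄_within) / (M/2) with M = n(n−1)/2, and a permutation
p-value with the +1 correction so p is never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr, rankdata

from .io import CountTable


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (self.matrix < -1e-12).any():
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


def _clean_abundances(abundances) -> np.ndarray:
    v = np.asarray(abundances, dtype=float)
    if v.ndim != 1:
        raise ValueError("abundance vector must be 1-dimensional")
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    if v.sum() == 0:
        raise ValueError("all-zero abundance vector")
    return v


def shannon(abundances) -> float:
    """Shannon entropy H = −Σ p ln p (nats) of the normalized abundances."""
    v = _clean_abundances(abundances)
    p = v[v > 0] / v.sum()
    return float(-(p * np.log(p)).sum())


def richness(abundances) -> int:
    """Number of taxa with positive abundance."""
    v = _clean_abundances(abundances)
    return int((v > 0).sum())


def pielou(abundances) -> float:
    """Evenness H / ln S; defined as 1 for a single-taxon sample."""
    s = richness(abundances)
    if s == 1:
        return 1.0
    return shannon(abundances) / np.log(s)


def alpha_diversity(table: CountTable) -> "np.ndarray":
    """Per-sample (shannon, richness, pielou) as a structured summary."""
    import pandas as pd

    rows = []
    for j, sid in enumerate(table.sample_ids):
        col = table.values[:, j]
        rows.append(
            {
                "sample_id": sid,
                "shannon": shannon(col),
                "richness": richness(col),
                "pielou": pielou(col),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(a,b) = Σ|x_a − x_b| / Σ(x_a + x_b) between samples."""
    if table.n_samples < 2:
        raise ValueError("need at least two samples")
    zero = table.library_sizes == 0
    if zero.sum() >= 2:
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise ValueError(f"all-zero sample pair among {bad}")
    d = squareform(pdist(table.values.T, metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), d)


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    m = ranks.size
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    dist: DistanceMatrix,
    groups,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Analysis of similarities on a distance matrix.

    Returns (R, p). R compares mean between-group and within-group distance
    ranks; p = (1 + #{R_perm ≥ R_obs}) / (1 + n_perm).
    """
    labels = np.asarray(groups)
    if labels.shape[0] != dist.n:
        raise ValueError("group labels must match the distance matrix samples")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        small = uniq[counts < 2][0]
        raise ValueError(f"group {small!r} has fewer than two members")
    ranks = rankdata(dist.condensed())
    iu, ju = np.triu_indices(dist.n, k=1)
    codes = np.searchsorted(uniq, labels)
    within = codes[iu] == codes[ju]
    r_obs = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        hits += _anosim_r(ranks, perm[iu] == perm[ju]) >= r_obs
    p = (1 + hits) / (1 + n_perm)
    return r_obs, float(p)


def _classical_scaling(d: np.ndarray, k: int) -> np.ndarray:
    """Torgerson metric scaling used as the NMDS starting configuration."""
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:k]
    lam = np.clip(w[order], 0, None)
    return v[:, order] * np.sqrt(lam)


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    seed: int | None = None,
    n_restarts: int = 20,
    max_iter: int = 300,
) -> tuple[np.ndarray, float, bool]:
    """Nonmetric multidimensional scaling minimizing Kruskal stress-1.

    Runs once from a classical-scaling start plus `n_restarts` random starts
    and keeps the lowest-stress solution. Returns (coordinates, stress,
    converged); coordinates are defined only up to rotation/reflection/
    translation.
    """
    from sklearn.manifold import MDS

    if not k < dist.n:
        raise ValueError("k must be smaller than the number of samples")
    d = dist.matrix
    best_coords, best_stress = None, np.inf
    inits = [_classical_scaling(d, k)] + [None] * n_restarts
    rng = np.random.default_rng(seed)
    for init in inits:
        mds = MDS(
            n_components=k,
            metric=False,
            dissimilarity="precomputed",
            n_init=1,
            max_iter=max_iter,
            random_state=int(rng.integers(2**31 - 1)),
            normalized_stress=True,
            eps=1e-9,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = mds.fit_transform(d, init=init)
        if mds.stress_ < best_stress:
            best_stress, best_coords = float(mds.stress_), coords
    converged = np.isfinite(best_stress)
    if not converged:
        warnings.warn("NMDS did not converge; returning best configuration found")
    return best_coords, best_stress, converged


def matrix_correlation(d1: DistanceMatrix, d2: DistanceMatrix) -> float:
    """Pearson correlation of the strictly-lower-triangle entries of two matrices."""
    if d1.sample_ids != d2.sample_ids:
        raise ValueError("distance matrices are over different sample sets")
    il = np.tril_indices(d1.n, k=-1)
    return float(pearsonr(d1.matrix[il], d2.matrix[il])[0])
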