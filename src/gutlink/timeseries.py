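"""Pairwise discrete-time interaction inference from daily count series.

For taxa i and j the one-day change in log relative abundance of i is
modeled as

    x_{i,t+1} − x_{i,t} = α_{ij} + β_{ij} · x_{j,t}

fitted by OLS separately for every ordered pair, yielding a nonsymmetric
n×n coefficient matrix. β_{ij} is read as the biotic effect of j on i: a
positive significant coefficient means cooperation/commensalism, negative
competition/amensalism, and an opposite-signed significant pair parasitism.
Diagonal models (i on itself) are computed to mirror the n² system but the
independent variable is part of the dependent one, so they are excluded
from every downstream summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .io import CountTable, SampleMetadata, TaxonomyTable


@dataclass
class LogAbundanceSeries:
    """Log relative abundances of all taxa over strictly increasing days.

    ``x`` has shape (n_taxa, n_days); a pseudocount keeps every value finite.
    """

    taxa_ids: list[str]
    days: np.ndarray
    x: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("log abundances must be finite")
        if self.x.shape != (len(self.taxa_ids), len(self.days)):
            raise ValueError("x shape does not match taxa/days")

    def transitions(self) -> np.ndarray:
        """Indices t such that day[t+1] == day[t] + 1 (one-day transitions).

        Gaps in the sampling calendar simply drop the spanning transition:
        the model is a one-day map.
        """
        return np.flatnonzero(np.diff(self.days) == 1)


def to_log_relative(
    table: CountTable, metadata: SampleMetadata, pseudocount: float = 0.5
) -> LogAbundanceSeries:
    """x_{i,t} = ln((count + pc) / (library + S·pc)) over day-ordered fecal samples."""
    sample_ids, days = metadata.fecal_ids_by_day()
    sample_ids = [s for s in sample_ids if s in set(table.sample_ids)]
    if not sample_ids:
        raise ValueError("no fecal samples present in the count table")
    days = np.asarray(
        [int(metadata.frame.at[s, "day"]) for s in sample_ids], dtype=int
    )
    sub = table.select_samples(sample_ids)
    libs = sub.library_sizes
    x = np.log((sub.values + pseudocount) / (libs + sub.n_taxa * pseudocount))
    return LogAbundanceSeries(list(sub.taxa_ids), days, x, pseudocount)


@dataclass
class InteractionMatrix:
    """All ordered-pair model fits: intercepts, coefficients, raw and BH p."""

    taxa_ids: list[str]
    alpha: np.ndarray
    beta: np.ndarray
    p_raw: np.ndarray
    p_bh: np.ndarray  # NaN on the diagonal (excluded from adjustment)
    degenerate: np.ndarray = field(default=None)

    @property
    def n(self) -> int:
        return len(self.taxa_ids)

    def offdiag_mask(self) -> np.ndarray:
        return ~np.eye(self.n, dtype=bool)

    def significant(self, alpha: float = 0.01) -> np.ndarray:
        """Off-diagonal models with BH-adjusted p below `alpha`."""
        with np.errstate(invalid="ignore"):
            return (self.p_bh < alpha) & self.offdiag_mask()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ti in enumerate(self.taxa_ids):
            for j, tj in enumerate(self.taxa_ids):
                if i == j:
                    continue
                rows.append(
                    {
                        "target": ti,
                        "source": tj,
                        "alpha": self.alpha[i, j],
                        "beta": self.beta[i, j],
                        "p_raw": self.p_raw[i, j],
                        "p_bh": self.p_bh[i, j],
                    }
                )
        return pd.DataFrame(rows)


def fit_pair(x_i: np.ndarray, x_j: np.ndarray) -> tuple[float, float, float]:
    """OLS fit of Δx_i on x_j for one ordered pair of aligned series.

    Inputs are the full series (length T); the response uses consecutive
    differences. Returns (alpha, beta, p). A zero-variance predictor is
    degenerate: (mean Δx, 0, 1).
    """
    x_i = np.asarray(x_i, float)
    x_j = np.asarray(x_j, float)
    dy = np.diff(x_i)
    xp = x_j[:-1]
    return _fit_one(xp, dy)


def _fit_one(xp: np.ndarray, dy: np.ndarray) -> tuple[float, float, float]:
    if len(dy) < 3:
        raise ValueError("need at least 3 usable transitions")
    xc = xp - xp.mean()
    ssx = (xc**2).sum()
    if ssx == 0:
        return float(dy.mean()), 0.0, 1.0
    beta = (xc * (dy - dy.mean())).sum() / ssx
    alpha = dy.mean() - beta * xp.mean()
    resid = dy - alpha - beta * xp
    dof = len(dy) - 2
    s2 = (resid**2).sum() / dof
    se = np.sqrt(s2 / ssx)
    if se == 0:
        p = 0.0 if beta != 0 else 1.0
    else:
        p = 2 * t_dist.sf(abs(beta) / se, dof)
    return float(alpha), float(beta), float(p)


def _fit_all_pairs(
    resp: np.ndarray, pred: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of every response column on every predictor column.

    resp: (m, n) one-day changes per target taxon; pred: (m, n) predictor
    levels per source taxon. Returns alpha, beta, p, degenerate — all (n, n)
    indexed [target, source].
    """
    m, n = resp.shape
    dof = m - 2
    pc = pred - pred.mean(axis=0)
    rc = resp - resp.mean(axis=0)
    ssx = (pc**2).sum(axis=0)  # per source
    degenerate = ssx == 0
    ssx_safe = np.where(degenerate, 1.0, ssx)
    # cross[i, j] = Σ_t rc[t, i] · pc[t, j]
    cross = rc.T @ pc
    beta = cross / ssx_safe[None, :]
    beta[:, degenerate] = 0.0
    alpha = resp.mean(axis=0)[:, None] - beta * pred.mean(axis=0)[None, :]
    ssy = (rc**2).sum(axis=0)
    rss = np.maximum(ssy[:, None] - beta**2 * ssx_safe[None, :], 0.0)
    s2 = rss / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2 / ssx_safe[None, :])
        tstat = np.where(se > 0, np.abs(beta) / se, np.inf)
    p = 2 * t_dist.sf(tstat, dof)
    p = np.where((se == 0) & (beta == 0), 1.0, p)
    p[:, degenerate] = 1.0
    return alpha, beta, p, np.broadcast_to(degenerate, (n, n)).copy()


def _bh_offdiag(p: np.ndarray) -> np.ndarray:
    """BH step-up over the off-diagonal entries; diagonal left NaN."""
    n = p.shape[0]
    off = ~np.eye(n, dtype=bool)
    adj = np.full_like(p, np.nan)
    adj[off] = multipletests(p[off], method="fdr_bh")[1]
    return adj


def build_interaction_matrix(
    series: LogAbundanceSeries, min_transitions: int = 10
) -> InteractionMatrix:
    """Fit all n² ordered-pair models; BH-adjust the n²−n off-diagonal p-values."""
    if len(series.taxa_ids) < 2:
        raise ValueError("need at least two taxa")
    trans = series.transitions()
    if len(trans) < min_transitions:
        raise ValueError(
            f"only {len(trans)} usable one-day transitions; need ≥{min_transitions}"
        )
    resp = (series.x[:, trans + 1] - series.x[:, trans]).T  # (m, n)
    pred = series.x[:, trans].T
    alpha, beta, p, degenerate = _fit_all_pairs(resp, pred)
    return InteractionMatrix(
        list(series.taxa_ids), alpha, beta, p, _bh_offdiag(p), degenerate
    )


# ---------------------------------------------------------------------------
# ecological classification of unordered pairs

CATEGORIES = (
    "cooperation",
    "competition",
    "commensalism",
    "amensalism",
    "parasitism",
    "none",
)


def classify_pair(
    beta_ij: float, sig_ij: bool, beta_ji: float, sig_ji: bool
) -> str:
    """Map the two directed coefficients of a pair to an ecological category.

    +/+ cooperation, −/− competition, +/0 commensalism, −/0 amensalism,
    +/− parasitism, 0/0 none (0 meaning not significant).
    """
    signs = []
    for b, s in ((beta_ij, sig_ij), (beta_ji, sig_ji)):
        signs.append(0 if not s else (1 if b > 0 else -1))
    a, b = sorted(signs)
    if (a, b) == (1, 1):
        return "cooperation"
    if (a, b) == (-1, -1):
        return "competition"
    if (a, b) == (0, 1):
        return "commensalism"
    if (a, b) == (-1, 0):
        return "amensalism"
    if (a, b) == (-1, 1):
        return "parasitism"
    return "none"


def classify_interactions(
    matrix: InteractionMatrix, alpha: float = 0.01
) -> pd.DataFrame:
    """Categorize every unordered taxon pair from its two directed models."""
    sig = matrix.significant(alpha)
    rows = []
    for i in range(matrix.n):
        for j in range(i + 1, matrix.n):
            rows.append(
                {
                    "taxon_a": matrix.taxa_ids[i],
                    "taxon_b": matrix.taxa_ids[j],
                    "beta_ab": matrix.beta[i, j],
                    "beta_ba": matrix.beta[j, i],
                    "category": classify_pair(
                        matrix.beta[i, j], sig[i, j], matrix.beta[j, i], sig[j, i]
                    ),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# permutation robustness


def permutation_null(
    series: LogAbundanceSeries,
    n_perm: int = 100,
    seed: int | None = None,
    alpha: float = 0.01,
) -> dict:
    """Refit all models after permuting the time order of each predictor series.

    Each replicate independently permutes every predictor column, refits the
    full set of ordered-pair models and BH-adjusts. Returns per-pair p
    averaged over replicates (both raw and adjusted), the pooled raw
    off-diagonal p-values, and the count of significant off-diagonal models
    per replicate.
    """
    rng = np.random.default_rng(seed)
    trans = series.transitions()
    resp = (series.x[:, trans + 1] - series.x[:, trans]).T
    pred = series.x[:, trans].T
    m, n = pred.shape
    off = ~np.eye(n, dtype=bool)
    sum_p_raw = np.zeros((n, n))
    sum_p_bh = np.zeros((n, n))
    sig_counts = []
    pooled = []
    for _ in range(n_perm):
        perm_pred = np.empty_like(pred)
        for j in range(n):
            perm_pred[:, j] = pred[rng.permutation(m), j]
        _, _, p, _ = _fit_all_pairs(resp, perm_pred)
        p_bh = _bh_offdiag(p)
        sum_p_raw += p
        sum_p_bh += np.nan_to_num(p_bh)
        sig_counts.append(int((p_bh[off] < alpha).sum()))
        pooled.append(p[off])
    return {
        "mean_p_raw": sum_p_raw / n_perm,
        "mean_p_bh": sum_p_bh / n_perm,
        "pooled_p_raw": np.concatenate(pooled),
        "significant_per_replicate": np.array(sig_counts),
        "n_perm": n_perm,
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# within- vs between-taxon coefficient contrast


def taxonomic_contrast(
    matrix: InteractionMatrix,
    taxonomy: TaxonomyTable,
    rank: str,
    alpha: float = 0.01,
) -> dict:
    """Compare significant β for pairs within vs between groups at a rank.

    One-sided Wilcoxon rank-sum with the alternative that within-group
    coefficients are more negative (competition among relatives is more
    intense).
    """
    labels = taxonomy.rank_labels(matrix.taxa_ids, rank)
    sig = matrix.significant(alpha)
    within, between = [], []
    for i in range(matrix.n):
        for j in range(matrix.n):
            if i == j or not sig[i, j]:
                continue
            (within if labels[i] == labels[j] else between).append(matrix.beta[i, j])
    if not within or not between:
        raise ValueError(
            f"empty partition at rank {rank!r}: "
            f"{len(within)} within, {len(between)} between"
        )
    stat, p = mannwhitneyu(within, between, alternative="less")
    return {
        "rank": rank,
        "mean_within": float(np.mean(within)),
        "mean_between": float(np.mean(between)),
        "n_within": len(within),
        "n_between": len(between),
        "statistic": float(stat),
        "p_one_sided": float(p),
    }
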