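"""Cross-modal concordance between time-series interactions and cooccurrence.

Two families of comparison link the temporal interaction matrix to the
symmetric cooccurrence matrices:

* scatter relationships — the directed regression coefficients β against
  the corresponding pairwise correlation coefficients (Spearman's rho or
  Pearson's r over the paired vectors);
* partitioned distributions — the correlation coefficients of unordered
  pairs split by whether the pair has a significant time-series model, the
  headline check being a positive location shift of the significant
  partition of *spatial* correlations (competing taxa that are actually
  colocalized).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import mannwhitneyu, pearsonr, spearmanr, wilcoxon

from .cooccur import CorrelationMatrix
from .timeseries import InteractionMatrix


def _aligned_vectors(
    beta: InteractionMatrix, corr: CorrelationMatrix
) -> tuple[np.ndarray, np.ndarray]:
    if beta.taxa_ids != corr.taxa_ids:
        raise ValueError("interaction and correlation matrices index different taxa")
    off = beta.offdiag_mask()
    return beta.beta[off], corr.matrix[off]


def coefficient_vs_correlation(
    beta: InteractionMatrix,
    corr: CorrelationMatrix,
    method: str = "spearman_rho",
) -> tuple[float, float]:
    """Association between directed β and the pair's correlation coefficient.

    Every ordered off-diagonal pair contributes one point; the symmetric
    correlation therefore enters twice per unordered pair, once per
    direction.
    """
    b, c = _aligned_vectors(beta, corr)
    if method == "spearman_rho":
        stat, p = spearmanr(b, c)
    elif method == "pearson_r":
        stat, p = pearsonr(b, c)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(p)


def pair_significance_mask(
    beta: InteractionMatrix, alpha: float = 0.01, rule: str = "either"
) -> np.ndarray:
    """Boolean (n, n) symmetric mask of significant unordered pairs.

    `rule` = "either" (default) marks a pair when at least one of its two
    directed models is significant; "both" requires both.
    """
    sig = beta.significant(alpha)
    if rule == "either":
        return sig | sig.T
    if rule == "both":
        return sig & sig.T
    raise ValueError(f"unknown rule {rule!r}")


def partition_by_significance(
    corr: CorrelationMatrix, sig_mask: np.ndarray
) -> dict:
    """Split unordered-pair correlations by time-series significance.

    Returns both distributions, their means, the two-sample Wilcoxon
    rank-sum p for a location difference, and a one-sample signed-rank p of
    the significant partition against zero.
    """
    n = corr.n
    iu = np.triu_indices(n, k=1)
    vals = corr.matrix[iu]
    sig = sig_mask[iu]
    dist_sig, dist_nonsig = vals[sig], vals[~sig]
    if len(dist_sig) == 0 or len(dist_nonsig) == 0:
        raise ValueError(
            f"empty partition: {len(dist_sig)} significant, "
            f"{len(dist_nonsig)} nonsignificant pairs"
        )
    _, p_shift = mannwhitneyu(dist_sig, dist_nonsig, alternative="two-sided")
    nonzero = dist_sig[dist_sig != 0]
    p_zero = float(wilcoxon(nonzero)[1]) if len(nonzero) else 1.0
    return {
        "dist_sig": dist_sig,
        "dist_nonsig": dist_nonsig,
        "mean_sig": float(dist_sig.mean()),
        "mean_nonsig": float(dist_nonsig.mean()),
        "n_sig": int(len(dist_sig)),
        "n_nonsig": int(len(dist_nonsig)),
        "wilcoxon_p": float(p_shift),
        "wilcoxon_p_vs_zero": p_zero,
    }


def concordance_report(
    beta: InteractionMatrix,
    temporal_spearman: CorrelationMatrix | None = None,
    temporal_sparcc: CorrelationMatrix | None = None,
    spatial_spearman: CorrelationMatrix | None = None,
    spatial_sparcc: CorrelationMatrix | None = None,
    alpha: float = 0.01,
    rule: str = "either",
) -> dict:
    """JSON-ready summary of all cross-modal comparisons.

    For each available correlation matrix: the partitioned-distribution test
    and the β-vs-correlation scatter statistics. Additionally the
    temporal-vs-spatial correlation scatters when both flavors of a method
    are present. Missing inputs are marked absent (None).
    """
    sig_mask = pair_significance_mask(beta, alpha, rule)
    matrices = {
        "temporal_spearman": temporal_spearman,
        "temporal_sparcc": temporal_sparcc,
        "spatial_spearman": spatial_spearman,
        "spatial_sparcc": spatial_sparcc,
    }
    report: dict = {"alpha": alpha, "pair_rule": rule, "partitions": {}, "scatter": {}}
    for name, corr in matrices.items():
        if corr is None:
            report["partitions"][name] = None
            report["scatter"][name] = None
            continue
        part = partition_by_significance(corr, sig_mask)
        report["partitions"][name] = {
            k: v for k, v in part.items() if not k.startswith("dist_")
        }
        rho, p_rho = coefficient_vs_correlation(beta, corr, "spearman_rho")
        r, p_r = coefficient_vs_correlation(beta, corr, "pearson_r")
        report["scatter"][name] = {
            "spearman_rho": rho,
            "spearman_p": p_rho,
            "pearson_r": r,
            "pearson_p": p_r,
        }
    for method in ("spearman", "sparcc"):
        tkey, skey = f"temporal_{method}", f"spatial_{method}"
        out_key = f"temporal_vs_spatial_{method}"
        tm, sm = matrices[tkey], matrices[skey]
        if tm is None or sm is None:
            report["scatter"][out_key] = None
            continue
        if tm.taxa_ids != sm.taxa_ids:
            raise ValueError("temporal and spatial matrices index different taxa")
        iu = np.triu_indices(tm.n, k=1)
        r, p = pearsonr(tm.matrix[iu], sm.matrix[iu])
        report["scatter"][out_key] = {"pearson_r": float(r), "pearson_p": float(p)}
    return report
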