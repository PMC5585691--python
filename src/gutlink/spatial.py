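"""Six-category spatial classification of OTU profiles along the GI tract.

Each OTU's relative abundance over 7 biopsy sites × 3 replicates is tested
for:

* a monotonic linear trend (MGA ascending / MGD descending toward the
  rectum), under two positional conventions — anatomical distance and
  ordinal site index;
* a "broken stick" profile whose slope changes sign at an interior site
  (GAB/GDB), via a continuous hinge (segmented) regression;
* single-site enrichment/depletion (habitat specialist HS / avoider HA),
  via an exact test for a difference in means of two groups of negative
  binomially distributed raw counts (common dispersion estimated by
  conditional maximum likelihood on library-equalized counts).

Categories are not exclusive across tests: one OTU may be, e.g., both MGD
and HS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .io import SITES, SITE_DISTANCE_CM, CountTable, SampleMetadata

#: interior sites eligible as breakpoint candidates
BREAKPOINT_SITES = ("AC", "TC", "DC")

ORDINAL = {s: k + 1 for k, s in enumerate(SITES)}  # TI=1 … R=7


@dataclass
class SiteProfile:
    """Relative abundances of one OTU at each (site, replicate) observation."""

    otu_id: str
    sites: list[str]  # one entry per observation
    abundance: np.ndarray

    def positions(self, convention: str) -> np.ndarray:
        """Observation positions, oriented so larger = closer to the rectum.

        ``ordinal`` uses 1..7 from TI to R; ``distance_cm`` uses the negated
        anatomical distance from the anus, so an abundance increase toward
        the rectum has positive slope under both conventions.
        """
        if convention == "ordinal":
            return np.array([ORDINAL[s] for s in self.sites], dtype=float)
        if convention == "distance_cm":
            return np.array([-SITE_DISTANCE_CM[s] for s in self.sites])
        raise ValueError(f"unknown positional convention {convention!r}")


def site_profiles(table: CountTable, metadata: SampleMetadata) -> list[SiteProfile]:
    """Build per-OTU site profiles (relative abundances) from biopsy samples."""
    layout = metadata.biopsy_layout()
    sample_ids = [s for s in layout["sample_id"] if s in table.sample_ids]
    if not sample_ids:
        raise ValueError("no biopsy samples present in the count table")
    sub = table.select_samples(sample_ids)
    rel = sub.relative_abundance()
    sites = [str(layout.at[s, "site"]) for s in sample_ids]
    return [
        SiteProfile(otu, list(sites), rel[i]) for i, otu in enumerate(sub.taxa_ids)
    ]


# ---------------------------------------------------------------------------
# linear trend (MGA / MGD)


def _ols(x: np.ndarray, y: np.ndarray):
    """Slope, two-sided p and intercept for y ~ x via normal equations."""
    n = len(x)
    xc = x - x.mean()
    yc = y - y.mean()
    ssx = (xc**2).sum()
    slope = (xc * yc).sum() / ssx
    intercept = y.mean() - slope * x.mean()
    resid = yc - slope * xc
    dof = n - 2
    s2 = (resid**2).sum() / dof
    se = math.sqrt(s2 / ssx)
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = 2 * t_dist.sf(abs(slope / se), dof)
    return slope, float(p), intercept


def fit_monotonic_trend(
    profile: SiteProfile, convention: str = "ordinal"
) -> dict:
    """OLS of relative abundance on position; all replicate points are used."""
    y = profile.abundance
    if np.ptp(y) == 0:
        return {
            "convention": convention,
            "slope": 0.0,
            "p": 1.0,
            "degenerate": True,
        }
    x = profile.positions(convention)
    slope, p, _ = _ols(x, y)
    return {"convention": convention, "slope": slope, "p": p, "degenerate": False}


def classify_gradient(trend: dict, alpha: float = 0.05) -> str | None:
    """MGA for a significant rectum-ward increase, MGD for a decrease."""
    if trend["degenerate"] or trend["p"] >= alpha:
        return None
    return "MGA" if trend["slope"] > 0 else "MGD"


# ---------------------------------------------------------------------------
# broken-stick (GAB / GDB)


def fit_breakpoint_model(profile: SiteProfile, breakpoint_site: str) -> dict:
    """Continuous two-segment linear model with a hinge at an interior site.

    Fits abundance ~ position + max(0, position − breakpoint) on ordinal
    positions; p_break is the two-sided p-value of the hinge term, i.e. of
    the slope change between the two segments.
    """
    if breakpoint_site not in BREAKPOINT_SITES:
        raise ValueError(
            f"breakpoint site must be interior ({BREAKPOINT_SITES}), "
            f"got {breakpoint_site!r}"
        )
    y = profile.abundance
    if np.ptp(y) == 0:
        return {
            "site": breakpoint_site,
            "slope_left": 0.0,
            "slope_right": 0.0,
            "p_break": 1.0,
            "degenerate": True,
        }
    x = profile.positions("ordinal")
    bp = ORDINAL[breakpoint_site]
    hinge = np.maximum(0.0, x - bp)
    X = np.column_stack([np.ones_like(x), x, hinge])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    s2 = (resid**2).sum() / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se_h = math.sqrt(max(cov[2, 2], 0.0))
    scale = max(np.abs(y).max(), 1e-300)
    if se_h <= 1e-12 * scale:  # exact piecewise/linear fit
        p_break = 1.0 if abs(beta[2]) <= 1e-10 * scale else 0.0
    else:
        p_break = 2 * t_dist.sf(abs(beta[2] / se_h), dof)
    return {
        "site": breakpoint_site,
        "slope_left": float(beta[1]),
        "slope_right": float(beta[1] + beta[2]),
        "p_break": float(p_break),
        "degenerate": False,
    }


def classify_breakpoint(fit: dict, alpha: float = 0.05) -> str | None:
    """GAB/GDB when the hinge is significant and the segment slopes change sign.

    Convention: "ascending"/"descending" names the post-breakpoint,
    rectum-ward segment — GAB falls then rises toward the rectum (a trough,
    slopes −/+), GDB rises then falls (a peak, slopes +/−). Segment slopes
    are reported so the call can be audited.
    """
    if fit["degenerate"] or fit["p_break"] >= alpha:
        return None
    left, right = fit["slope_left"], fit["slope_right"]
    if left < 0 < right:
        return "GAB"
    if right < 0 < left:
        return "GDB"
    return None


# ---------------------------------------------------------------------------
# negative-binomial exact test (HS / HA)


def _cml_dispersion(counts: np.ndarray, group_masks: list[np.ndarray]) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    `counts` are library-equalized pseudo-counts (OTUs × samples). The
    conditional log-likelihood given each group's total does not involve the
    mean, so a single dispersion is profiled over all OTUs and groups.
    """

    def neg_cll(delta: float) -> float:
        phi = delta / (1 - delta)
        r = 1.0 / phi
        total = 0.0
        for mask in group_masks:
            y = counts[:, mask]
            n = mask.sum()
            z = y.sum(axis=1)
            total += (
                gammaln(y + r).sum()
                + len(z) * gammaln(n * r)
                - gammaln(z + n * r).sum()
                - y.size * gammaln(r)
            )
        return -total

    res = minimize_scalar(neg_cll, bounds=(1e-6, 0.95), method="bounded")
    delta = float(res.x)
    return delta / (1 - delta)


def _q2q_nbinom(
    y: np.ndarray, mu_in: np.ndarray, mu_out: np.ndarray, phi: float
) -> np.ndarray:
    """Quantile-map counts between library sizes at a given dispersion.

    Average of a normal and a gamma quantile-quantile transformation, which
    tracks the NB distribution well over the count range seen here.
    """
    from scipy.stats import gamma as gamma_dist

    eps = 1e-10
    mu_in = np.maximum(mu_in, 0.25)
    mu_out = np.maximum(mu_out, 0.25)
    ri = 1 + phi * mu_in
    ro = 1 + phi * mu_out
    q1 = mu_out + np.sqrt((mu_out * ro) / (mu_in * ri)) * (y - mu_in)
    p = gamma_dist.cdf(y, a=mu_in / ri, scale=ri)
    q2 = gamma_dist.ppf(np.clip(p, eps, 1 - eps), a=mu_out / ro, scale=ro)
    return np.maximum((q1 + q2) / 2.0, 0.0)


def _equalize_libraries(
    values: np.ndarray, group_masks: list[np.ndarray], phi: float
) -> tuple[np.ndarray, float]:
    """Pseudo-counts at a common (geometric-mean) library size."""
    libs = values.sum(axis=0)
    common = float(np.exp(np.mean(np.log(libs))))
    pseudo = np.empty_like(values, dtype=float)
    for mask in group_masks:
        group_lambda = values[:, mask].sum(axis=1) / libs[mask].sum()
        mu_in = np.outer(group_lambda, libs[mask])
        mu_out = np.outer(group_lambda, np.full(mask.sum(), common))
        pseudo[:, mask] = _q2q_nbinom(values[:, mask], mu_in, mu_out, phi)
    return pseudo, common


def _exact_nb_p(s1: int, s2: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact p for a mean difference of two NB groups.

    Conditions on the pooled total and sums the probabilities of all splits
    as or less likely than the observed one. In the dispersion → 0 limit the
    conditional distribution is binomial(total, n1/(n1+n2)).
    """
    total = s1 + s2
    if total == 0:
        return 1.0
    s = np.arange(total + 1)
    if phi < 1e-12:
        from scipy.stats import binom

        logp = binom.logpmf(s, total, n1 / (n1 + n2))
    else:
        from scipy.stats import nbinom

        m = total / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        mu1, mu2 = n1 * m, n2 * m
        logp = nbinom.logpmf(s, r1, r1 / (r1 + mu1)) + nbinom.logpmf(
            total - s, r2, r2 / (r2 + mu2)
        )
    logp -= logsumexp(logp)
    # tolerance admits outcomes tied with the observed one up to floating
    # error (exact ties are common: pmf ratios hit 1 at integer boundaries)
    cutoff = logp[s1] + 1e-4
    return float(min(1.0, np.exp(logsumexp(logp[logp <= cutoff]))))


def nb_exact_test(
    raw_counts: CountTable,
    metadata: SampleMetadata,
    site: str,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Exact test of each OTU's mean raw count at one site vs all other sites.

    Raw (unscaled) counts are required: library-size differences are handled
    inside the procedure by quantile equalization. When `dispersion` is None
    a common dispersion is estimated by conditional maximum likelihood
    (one round of equalize → profile → re-equalize).

    Returns a frame indexed by otu_id with columns p, direction (+1 enriched
    at the site, −1 depleted, 0 no data), and BH-adjusted fdr.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}")
    layout = metadata.biopsy_layout()
    sample_ids = [s for s in layout["sample_id"] if s in table_ids(raw_counts)]
    sub = raw_counts.select_samples(sample_ids)
    in_site = np.array([layout.at[s, "site"] == site for s in sample_ids])
    if in_site.sum() < 2 or (~in_site).sum() < 2:
        raise ValueError(f"need ≥2 samples inside and outside site {site}")
    masks = [in_site, ~in_site]

    if dispersion is None:
        phi = 0.01
        for _ in range(2):
            pseudo, _ = _equalize_libraries(sub.values, masks, phi)
            phi = _cml_dispersion(np.round(pseudo), masks)
    else:
        phi = float(dispersion)
    pseudo, _ = _equalize_libraries(sub.values, masks, phi)

    n1, n2 = int(in_site.sum()), int((~in_site).sum())
    s1 = np.round(pseudo[:, in_site].sum(axis=1)).astype(int)
    s2 = np.round(pseudo[:, ~in_site].sum(axis=1)).astype(int)
    pvals = np.array([_exact_nb_p(a, b, n1, n2, phi) for a, b in zip(s1, s2)])
    mean1 = s1 / n1
    mean2 = s2 / n2
    direction = np.sign(mean1 - mean2).astype(int)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "otu_id": sub.taxa_ids,
            "site": site,
            "p": pvals,
            "direction": direction,
            "fdr": fdr,
            "dispersion": phi,
        }
    ).set_index("otu_id")


def table_ids(table: CountTable) -> set[str]:
    return set(table.sample_ids)


def classify_specialist(
    results: pd.DataFrame, p_thresh: float = 0.01, fdr_thresh: float = 0.05
) -> pd.Series:
    """HS for significant enrichment at the tested site, HA for depletion."""
    sig = (results["p"] < p_thresh) & (results["fdr"] < fdr_thresh)
    out = pd.Series(index=results.index, dtype=object)
    out[sig & (results["direction"] > 0)] = "HS"
    out[sig & (results["direction"] < 0)] = "HA"
    return out


# ---------------------------------------------------------------------------
# orchestrator


def classify_spatial_patterns(
    raw_counts: CountTable,
    metadata: SampleMetadata,
    alpha_trend: float = 0.05,
    alpha_break: float = 0.05,
    p_hs: float = 0.01,
    fdr_hs: float = 0.05,
    specialist_sites=SITES,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Run all three spatial tests; one row per (otu, category) call.

    Trend and breakpoint tests run on relative abundances (convention-
    independent of scaling); the exact tests run on the raw counts given.
    """
    profiles = site_profiles(raw_counts, metadata)
    rows: list[dict] = []
    for prof in profiles:
        for convention in ("distance_cm", "ordinal"):
            trend = fit_monotonic_trend(prof, convention)
            cat = classify_gradient(trend, alpha_trend)
            if cat:
                rows.append(
                    {
                        "otu_id": prof.otu_id,
                        "category": cat,
                        "convention": convention,
                        "site": "",
                        "slope": trend["slope"],
                        "p": trend["p"],
                        "fdr": np.nan,
                    }
                )
        for bp in BREAKPOINT_SITES:
            fit = fit_breakpoint_model(prof, bp)
            cat = classify_breakpoint(fit, alpha_break)
            if cat:
                rows.append(
                    {
                        "otu_id": prof.otu_id,
                        "category": cat,
                        "convention": "ordinal",
                        "site": bp,
                        "slope": fit["slope_right"] - fit["slope_left"],
                        "p": fit["p_break"],
                        "fdr": np.nan,
                    }
                )
    for site in specialist_sites:
        res = nb_exact_test(raw_counts, metadata, site, dispersion=dispersion)
        calls = classify_specialist(res, p_hs, fdr_hs)
        for otu, cat in calls.dropna().items():
            rows.append(
                {
                    "otu_id": otu,
                    "category": cat,
                    "convention": "",
                    "site": site,
                    "slope": np.nan,
                    "p": res.at[otu, "p"],
                    "fdr": res.at[otu, "fdr"],
                }
            )
    return pd.DataFrame(
        rows, columns=["otu_id", "category", "convention", "site", "slope", "p", "fdr"]
    )
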