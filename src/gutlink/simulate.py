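"""Ground-truthed synthetic data with the statistical structure the analyses assume.

Two generators mirror the two arms of the study design:

* a daily fecal count time series produced by running the pairwise
  interaction model forward on log abundances — Gaussian process noise,
  compositional closure, then multinomial sequencing noise at a lognormal
  library size (two-layer noise, the standard generative picture for
  compositional count data);
* a 7-site × 3-replicate biopsy table whose taxa follow archetypes of the
  six spatial categories (linear ramps, hinge profiles, single-site spikes
  and dips) with negative-binomial count noise.

Every generator takes an explicit seed and returns its ground truth
(interaction matrix, category labels) so recovery can be scored.

Default sampling depths follow the study design being emulated: fecal
libraries lognormal with mean ≈ 139,000 reads (SD ≈ 71,000), biopsy
libraries with mean ≈ 60,000 (SD ≈ 40,000), 139 daily samples, triplicate
biopsies at seven sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SITES, SITE_DISTANCE_CM, CountTable, SampleMetadata, TaxonomyTable

#: spatial archetypes the generator can emit ("category" or "category@SITE")
GRADIENT_LABELS = ("MGA", "MGD")
SITED_LABELS = ("GAB", "GDB", "HS", "HA")


@dataclass
class SimulationConfig:
    """Knobs of both generators, with study-design defaults."""

    n_taxa: int = 20
    n_days: int = 139
    # fecal library size: lognormal matching mean 139,390 / SD 71,119 reads
    fecal_lib_meanlog: float = 11.729
    fecal_lib_sdlog: float = 0.481
    # biopsy library size: lognormal matching mean 59,831 / SD 39,922 reads
    biopsy_lib_meanlog: float = 10.815
    biopsy_lib_sdlog: float = 0.607
    # interaction structure
    n_pairs: int | None = None  # default: n_taxa // 2 disjoint pairs
    strength_range: tuple[float, float] = (0.55, 0.8)
    # reciprocal (-/- and +/+) pairs get one strong and one weak direction:
    # interaction strengths are typically highly asymmetric, and a pair of
    # strong mutually reinforcing couplings destabilizes the linear map
    weak_range: tuple[float, float] = (0.01, 0.03)
    self_regulation: float = -0.4
    process_noise_sd: float = 0.25
    # competition dominates, as observed in dense gut communities
    interaction_mix: dict = field(
        default_factory=lambda: {
            "competition": 0.6,
            "cooperation": 0.1,
            "commensalism": 0.15,
            "amensalism": 0.15,
        }
    )
    # spatial structure
    n_sites: int = 7
    n_replicates: int = 3
    nb_dispersion: float = 0.2
    effect_fold: float = 4.0
    # baseline weight of spatially structured taxa relative to the flat
    # bulk; keeping them a minority of community mass preserves the nominal
    # per-taxon fold after compositional closure
    structured_weight: float = 0.25
    niche_coupling: float = 0.0
    # taxonomy
    n_phyla: int = 4
    genera_per_phylum: int = 4
    seed: int | None = None


# ---------------------------------------------------------------------------
# interaction matrix ground truth


def make_interaction_matrix(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sparse signed β with negative self-regulation on the diagonal.

    Off-diagonal structure: disjoint taxon pairs, each assigned an
    ecological category from `interaction_mix`. The pair's dominant
    direction draws its magnitude from `strength_range`; for the reciprocal
    categories (competition, cooperation) the return direction draws from
    `weak_range`, and for the nonreciprocal ones it is zero.
    """
    n = config.n_taxa
    beta = np.zeros((n, n))
    np.fill_diagonal(beta, config.self_regulation)
    n_pairs = config.n_pairs if config.n_pairs is not None else n // 2
    order = rng.permutation(n)
    cats = list(config.interaction_mix)
    probs = np.array([config.interaction_mix[c] for c in cats], dtype=float)
    probs /= probs.sum()
    lo, hi = config.strength_range
    records = []
    for k in range(min(n_pairs, n // 2)):
        i, j = int(order[2 * k]), int(order[2 * k + 1])
        cat = cats[rng.choice(len(cats), p=probs)]
        mag_strong = rng.uniform(lo, hi)
        mag_weak = rng.uniform(*config.weak_range)
        if cat == "competition":
            b_ij, b_ji = -mag_strong, -mag_weak
        elif cat == "cooperation":
            b_ij, b_ji = mag_strong, mag_weak
        elif cat == "commensalism":
            b_ij, b_ji = mag_strong, 0.0
        else:  # amensalism
            b_ij, b_ji = -mag_strong, 0.0
        beta[i, j], beta[j, i] = b_ij, b_ji
        records.append(
            {"taxon_a": i, "taxon_b": j, "category": cat, "beta_ab": b_ij, "beta_ba": b_ji}
        )
    rad = np.max(np.abs(np.linalg.eigvals(np.eye(n) + beta)))
    if rad >= 1:
        raise ValueError(
            f"linearized map has spectral radius {rad:.3f} ≥ 1; "
            "use stronger (more negative) self-regulation or weaker interactions"
        )
    return beta, pd.DataFrame(records)


# ---------------------------------------------------------------------------
# fecal time series


def simulate_time_series(
    config: SimulationConfig,
    beta_true: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[CountTable, SampleMetadata, np.ndarray]:
    """Run the interaction model forward and sequence the result.

    Log abundances follow x_{t+1} = x_t + α + B x_t + ε with ε ~ N(0, σ²);
    α is set so the noise-free fixed point sits at taxon-specific baseline
    log abundances. Compositions are the closed (softmax) x, and counts are
    multinomial draws at a lognormal library size per day.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    n, T = config.n_taxa, config.n_days
    if beta_true is None:
        beta_true, _ = make_interaction_matrix(config, rng)
    beta_true = np.asarray(beta_true, dtype=float)
    baseline = rng.normal(0.0, 1.0, size=n)
    alpha = -beta_true @ baseline
    x = baseline.copy()
    # burn-in to reach the stationary regime before day 1
    for _ in range(50):
        x = x + alpha + beta_true @ x + rng.normal(0, config.process_noise_sd, n)
    xs = np.empty((n, T))
    for t in range(T):
        xs[:, t] = x
        x = x + alpha + beta_true @ x + rng.normal(0, config.process_noise_sd, n)
        if np.max(np.abs(x - baseline)) > 50:
            raise ValueError(
                "trajectory diverged; use stronger self-regulation "
                "(more negative diagonal) or weaker interactions"
            )
    comp = np.exp(xs - xs.max(axis=0))
    comp /= comp.sum(axis=0)
    libs = np.round(
        rng.lognormal(config.fecal_lib_meanlog, config.fecal_lib_sdlog, T)
    ).astype(int)
    counts = np.column_stack(
        [rng.multinomial(libs[t], comp[:, t]) for t in range(T)]
    )
    taxa = [f"OTU{i + 1}" for i in range(n)]
    samples = [f"F{t + 1:03d}" for t in range(T)]
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "sample_type": "fecal",
                "day": np.arange(1, T + 1),
            }
        )
    )
    return CountTable(counts, taxa, samples), meta, beta_true


# ---------------------------------------------------------------------------
# biopsy spatial table


def _parse_label(label: str) -> tuple[str, str | None]:
    if "@" in label:
        cat, site = label.split("@", 1)
    else:
        cat, site = label, None
    if cat in SITED_LABELS and site not in SITES:
        raise ValueError(f"label {label!r} needs a valid site, e.g. '{cat}@AC'")
    if cat not in GRADIENT_LABELS + SITED_LABELS + ("flat",):
        raise ValueError(f"unknown spatial label {label!r}")
    return cat, site


def archetype_profile(label: str, fold: float) -> np.ndarray:
    """Relative 7-site mean profile (TI→R) for one spatial archetype.

    `fold` is the max/min ratio of the profile. Gradients are linear in
    ordinal site position; GAB is a trough (falls then rises toward the
    rectum) and GDB a peak, hinged at the labeled site; HS/HA spike or dip
    at a single site.
    """
    cat, site = _parse_label(label)
    if cat == "flat":
        return np.ones(7)
    if fold <= 1:
        raise ValueError(f"non-flat label {label!r} requires effect fold > 1")
    if cat == "MGA":
        return np.linspace(1.0, fold, 7)
    if cat == "MGD":
        return np.linspace(fold, 1.0, 7)
    k = SITES.index(site)
    if cat == "GAB":
        prof = np.empty(7)
        prof[: k + 1] = np.linspace(fold, 1.0, k + 1)
        prof[k:] = np.linspace(1.0, fold, 7 - k)
        return prof
    if cat == "GDB":
        prof = np.empty(7)
        prof[: k + 1] = np.linspace(1.0, fold, k + 1)
        prof[k:] = np.linspace(fold, 1.0, 7 - k)
        return prof
    prof = np.ones(7)
    prof[k] = fold if cat == "HS" else 1.0 / fold
    return prof


def default_spatial_labels(n_taxa: int, rng: np.random.Generator) -> list[str]:
    """A mixed assignment: one taxon per archetype variant, the rest flat."""
    pool = ["MGA", "MGD"]
    pool += [f"{c}@{s}" for c in ("GAB", "GDB") for s in ("AC", "TC", "DC")]
    pool += [f"{c}@{s}" for c in ("HS", "HA") for s in ("TI", "AC", "R")]
    labels = list(pool[:n_taxa])
    labels += ["flat"] * (n_taxa - len(labels))
    rng.shuffle(labels)
    return labels


def simulate_spatial(
    config: SimulationConfig,
    labels: list[str] | None = None,
    seed: int | None = None,
    taxa_ids: list[str] | None = None,
) -> tuple[CountTable, SampleMetadata, pd.DataFrame]:
    """Biopsy-style counts from per-taxon spatial archetypes.

    Site compositions come from the archetype profiles (equal baseline
    weights, closed per site); each replicate's counts are independent
    negative-binomial draws around composition × library size at the
    configured dispersion.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    n = config.n_taxa
    if labels is None:
        labels = default_spatial_labels(n, rng)
    if len(labels) != n:
        raise ValueError("need one spatial label per taxon")
    prof = np.stack([archetype_profile(lab, config.effect_fold) for lab in labels])
    weights = np.array(
        [1.0 if lab == "flat" else config.structured_weight for lab in labels]
    )
    prof = prof * weights[:, None]
    comp = prof / prof.sum(axis=0)
    taxa = taxa_ids if taxa_ids is not None else [f"OTU{i + 1}" for i in range(n)]
    phi = config.nb_dispersion
    counts = np.zeros((n, 7 * config.n_replicates))
    meta_rows = []
    col = 0
    for k, site in enumerate(SITES):
        for rep in range(1, config.n_replicates + 1):
            lib = rng.lognormal(config.biopsy_lib_meanlog, config.biopsy_lib_sdlog)
            mu = comp[:, k] * lib
            if phi > 0:
                r = 1.0 / phi
                counts[:, col] = rng.negative_binomial(r, r / (r + mu))
            else:  # noise-free mode: expected counts, rounded
                counts[:, col] = np.round(mu)
            meta_rows.append(
                {
                    "sample_id": f"B_{site}_{rep}",
                    "sample_type": "biopsy",
                    "site": site,
                    "replicate": rep,
                    "distance_cm": SITE_DISTANCE_CM[site],
                }
            )
            col += 1
    meta = SampleMetadata(pd.DataFrame(meta_rows))
    truth = pd.DataFrame(
        {
            "otu_id": taxa,
            "label": labels,
            "category": [_parse_label(lab)[0] for lab in labels],
            "site": [_parse_label(lab)[1] or "" for lab in labels],
        }
    )
    sample_ids = [r["sample_id"] for r in meta_rows]
    return CountTable(counts, list(taxa), sample_ids), meta, truth


# ---------------------------------------------------------------------------
# taxonomy


def generate_taxonomy(
    taxa_ids: list[str],
    n_phyla: int = 4,
    genera_per_phylum: int = 4,
    seed: int | None = None,
) -> TaxonomyTable:
    """Hierarchical six-rank labels over the given OTU ids.

    Genera are assigned round-robin after a seeded shuffle, so every genus
    (and phylum) receives a balanced number of OTUs.
    """
    rng = np.random.default_rng(seed)
    genera = [
        (p, g) for p in range(n_phyla) for g in range(genera_per_phylum)
    ]
    order = rng.permutation(len(taxa_ids))
    rows = []
    for slot, idx in enumerate(order):
        p, g = genera[slot % len(genera)]
        rows.append(
            {
                "otu_id": taxa_ids[idx],
                "kingdom": "Bacteria",
                "phylum": f"Phylum{p + 1}",
                "class": f"Class{p + 1}",
                "order": f"Order{p + 1}_{g + 1}",
                "family": f"Family{p + 1}_{g + 1}",
                "genus": f"Genus{p + 1}_{g + 1}",
            }
        )
    frame = pd.DataFrame(rows)
    frame["__ord"] = [taxa_ids.index(o) for o in frame["otu_id"]]
    return TaxonomyTable(frame.sort_values("__ord").drop(columns="__ord"))


# ---------------------------------------------------------------------------
# linked study (time series + biopsies over the same taxa)


def simulate_paired_study(config: SimulationConfig, seed: int | None = None) -> dict:
    """One taxa set observed both temporally and spatially.

    Interacting pairs are generated first; with probability
    ``niche_coupling`` each *competing* pair is placed into the same spatial
    niche (both members share one archetype), which induces a positive
    spatial correlation for exactly the pairs the time-series analysis
    should flag — the resource-competition scenario. With coupling 0 the
    spatial labels are independent of the interaction structure.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    beta_true, pairs = make_interaction_matrix(config, rng)
    counts_fecal, meta_fecal, _ = simulate_time_series(
        config, beta_true=beta_true, seed=int(rng.integers(2**31 - 1))
    )
    taxa = counts_fecal.taxa_ids
    # shared niches must imply cooccurrence along the whole tract, so the
    # pool holds archetypes with distinct means at every site (gradients and
    # hinges); a shared single-site spike would leave six tied sites whose
    # ranks are pure noise.
    niche_pool = ["MGA", "MGD"] + [
        f"{c}@{s}" for c in ("GAB", "GDB") for s in ("AC", "TC", "DC")
    ]
    solo_pool = [f"{c}@{s}" for c in ("HS", "HA") for s in SITES]
    labels = [
        str(rng.choice(solo_pool)) if rng.random() < 0.4 else "flat"
        for _ in range(config.n_taxa)
    ]
    for rec in pairs.itertuples():
        if rec.category == "competition" and rng.random() < config.niche_coupling:
            shared = str(rng.choice(niche_pool))
            labels[rec.taxon_a] = shared
            labels[rec.taxon_b] = shared
    counts_biopsy, meta_biopsy, truth = simulate_spatial(
        config, labels=labels, seed=int(rng.integers(2**31 - 1)), taxa_ids=taxa
    )
    taxonomy = generate_taxonomy(
        taxa, config.n_phyla, config.genera_per_phylum, seed=int(rng.integers(2**31 - 1))
    )
    return {
        "counts_fecal": counts_fecal,
        "meta_fecal": meta_fecal,
        "counts_biopsy": counts_biopsy,
        "meta_biopsy": meta_biopsy,
        "taxonomy": taxonomy,
        "beta_true": beta_true,
        "pairs": pairs,
        "spatial_truth": truth,
    }
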