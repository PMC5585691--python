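"""End-to-end pipeline: normalize → filter → diversity → spatial → interactions
→ cooccurrence → concordance, driven by a YAML config.

Every stochastic stage takes an explicit seed from the config; a rerun with
the same config is bit-identical for deterministic stages. A manifest with
input hashes, parameters and seeds is written alongside the artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__, concordance, cooccur, diversity, prep, spatial, timeseries
from .io import (
    read_count_table,
    read_metadata,
    read_taxonomy,
    write_count_table,
)

logger = logging.getLogger(__name__)

DEFAULTS = {
    "prevalence_min_abund": 0.001,
    "prevalence_min_samples": 3,
    "consistency_min_abund": 0.0005,
    "consistency_min_frac": 0.9,
    "alpha_trend": 0.05,
    "alpha_break": 0.05,
    "p_hs": 0.01,
    "fdr_hs": 0.05,
    "interaction_alpha": 0.01,
    "pseudocount": 0.5,
    "anosim_permutations": 10_000,
    "permutation_replicates": 100,
    "sparcc_outer": 10,
    "sparcc_threshold": 0.1,
    "sparcc_inner": 20,
    "seed": 1,
}


class ConfigError(ValueError):
    """Raised when a pipeline config fails validation."""


def validate_config(cfg: dict) -> dict:
    merged = {**DEFAULTS, **cfg}
    for key in ("counts", "metadata"):
        if key not in merged:
            raise ConfigError(f"config missing required key {key!r}")
        if not Path(merged[key]).exists():
            raise ConfigError(f"input file not found: {merged[key]}")
    if "taxonomy" in merged and not Path(merged["taxonomy"]).exists():
        raise ConfigError(f"input file not found: {merged['taxonomy']}")
    for key in ("alpha_trend", "alpha_break", "p_hs", "fdr_hs", "interaction_alpha"):
        a = merged[key]
        if not (0 < a <= 1):
            raise ConfigError(f"{key}={a} outside (0, 1]")
    for key in ("prevalence_min_abund", "consistency_min_abund"):
        if not (0 <= merged[key] < 1):
            raise ConfigError(f"{key} must be a fraction in [0, 1)")
    if not (0 <= merged["consistency_min_frac"] <= 1):
        raise ConfigError("consistency_min_frac must be in [0, 1]")
    return merged


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config_path, out_dir) -> dict:
    """Run every stage the inputs support; return the manifest dict."""
    with open(config_path) as fh:
        cfg = validate_config(yaml.safe_load(fh) or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    table = read_count_table(cfg["counts"])
    meta = read_metadata(cfg["metadata"])
    taxonomy = read_taxonomy(cfg["taxonomy"]) if "taxonomy" in cfg else None

    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in cfg.items()},
        "inputs": {
            k: _sha256(cfg[k]) for k in ("counts", "metadata", "taxonomy") if k in cfg
        },
        "stages": {},
    }

    # normalization (diversity uses scaled + singleton-removed, no other filter)
    raw = table
    descaled = prep.remove_singletons(raw)
    scaled = prep.common_scale(descaled)
    write_count_table(scaled, out / "scaled.tsv")

    div = diversity.alpha_diversity(scaled)
    div.to_csv(out / "diversity.tsv", sep="\t")
    manifest["stages"]["diversity"] = {"n_samples": int(len(div))}

    types = meta.frame.loc[scaled.sample_ids, "sample_type"]
    results: dict = {}
    if (types == "biopsy").sum() >= 6:
        biopsy_ids = list(types.index[types == "biopsy"])
        biopsy_scaled = prep.filter_prevalence(
            prep.common_scale(raw.select_samples(biopsy_ids)),
            cfg["prevalence_min_abund"],
            cfg["prevalence_min_samples"],
        )
        dist = diversity.bray_curtis(biopsy_scaled)
        sites = meta.frame.loc[biopsy_scaled.sample_ids, "site"]
        r_stat, p = diversity.anosim(
            dist, sites.to_numpy(), n_perm=cfg["anosim_permutations"], seed=seed
        )
        manifest["stages"]["anosim_sites"] = {"R": r_stat, "p": p}
        biopsy_raw = raw.select_samples(biopsy_ids).select_taxa(
            [t for t in raw.taxa_ids if t in set(biopsy_scaled.taxa_ids)]
        )
        classes = spatial.classify_spatial_patterns(
            biopsy_raw,
            meta,
            alpha_trend=cfg["alpha_trend"],
            alpha_break=cfg["alpha_break"],
            p_hs=cfg["p_hs"],
            fdr_hs=cfg["fdr_hs"],
        )
        classes.to_csv(out / "spatial_classes.tsv", sep="\t", index=False)
        manifest["stages"]["spatial"] = {
            "n_otus": int(biopsy_raw.n_taxa),
            "n_calls": int(len(classes)),
        }
        results["biopsy_filtered"] = biopsy_raw

    if (types == "fecal").sum() >= 12:
        fecal_ids = list(types.index[types == "fecal"])
        fecal_scaled = prep.filter_consistency(
            prep.common_scale(raw.select_samples(fecal_ids)),
            cfg["consistency_min_abund"],
            cfg["consistency_min_frac"],
        )
        series = timeseries.to_log_relative(fecal_scaled, meta, cfg["pseudocount"])
        imat = timeseries.build_interaction_matrix(series)
        imat.to_frame().to_csv(out / "interactions.tsv", sep="\t", index=False)
        cats = timeseries.classify_interactions(imat, cfg["interaction_alpha"])
        cats.to_csv(out / "interaction_categories.tsv", sep="\t", index=False)
        null = timeseries.permutation_null(
            series, n_perm=cfg["permutation_replicates"], seed=seed
        )
        with open(out / "permutation_summary.json", "w") as fh:
            json.dump(
                {
                    "mean_pooled_p_raw": float(null["pooled_p_raw"].mean()),
                    "significant_per_replicate": null[
                        "significant_per_replicate"
                    ].tolist(),
                },
                fh,
                indent=2,
            )
        manifest["stages"]["interactions"] = {
            "n_taxa": imat.n,
            "n_models_offdiag": imat.n * (imat.n - 1),
            "n_significant": int(imat.significant(cfg["interaction_alpha"]).sum()),
        }
        if taxonomy is not None:
            try:
                contrast = timeseries.taxonomic_contrast(
                    imat, taxonomy, "phylum", cfg["interaction_alpha"]
                )
                manifest["stages"]["taxonomic_contrast"] = {
                    k: v for k, v in contrast.items()
                }
            except ValueError as e:
                logger.warning("taxonomic contrast skipped: %s", e)

        t_spear = cooccur.spearman_matrix(fecal_scaled, flavor="temporal")
        fecal_raw = raw.select_samples(fecal_ids).select_taxa(
            [t for t in raw.taxa_ids if t in set(fecal_scaled.taxa_ids)]
        )
        t_sparcc = cooccur.sparcc_matrix(
            fecal_raw,
            n_outer=cfg["sparcc_outer"],
            exclusion_threshold=cfg["sparcc_threshold"],
            n_inner=cfg["sparcc_inner"],
            seed=seed,
            flavor="temporal",
        )
        s_spear = s_sparcc = None
        if "biopsy_filtered" in results:
            shared = [
                t for t in fecal_scaled.taxa_ids
                if t in set(results["biopsy_filtered"].taxa_ids)
            ]
            if len(shared) >= 4:
                biopsy_shared = results["biopsy_filtered"].select_taxa(shared)
                prof = cooccur.spatial_profile_table(biopsy_shared, meta)
                s_spear = cooccur.spearman_matrix(prof, flavor="spatial")
                s_sparcc = cooccur.sparcc_matrix(
                    biopsy_shared,
                    n_outer=cfg["sparcc_outer"],
                    exclusion_threshold=cfg["sparcc_threshold"],
                    n_inner=cfg["sparcc_inner"],
                    seed=seed + 1,
                    flavor="spatial",
                )
                imat_shared = _subset_interactions(imat, shared)
                t_spear_s = _subset_corr(t_spear, shared)
                t_sparcc_s = _subset_corr(t_sparcc, shared)
                report = concordance.concordance_report(
                    imat_shared,
                    temporal_spearman=t_spear_s,
                    temporal_sparcc=t_sparcc_s,
                    spatial_spearman=s_spear,
                    spatial_sparcc=s_sparcc,
                    alpha=cfg["interaction_alpha"],
                )
                with open(out / "concordance.json", "w") as fh:
                    json.dump(report, fh, indent=2)
                manifest["stages"]["concordance"] = {
                    "n_shared_taxa": len(shared)
                }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def _subset_corr(corr, taxa):
    idx = [corr.taxa_ids.index(t) for t in taxa]
    m = corr.matrix[np.ix_(idx, idx)]
    return cooccur.CorrelationMatrix(list(taxa), m, corr.method, corr.flavor)


def _subset_interactions(imat, taxa):
    idx = [imat.taxa_ids.index(t) for t in taxa]
    ix = np.ix_(idx, idx)
    return timeseries.InteractionMatrix(
        list(taxa),
        imat.alpha[ix],
        imat.beta[ix],
        imat.p_raw[ix],
        imat.p_bh[ix],
        imat.degenerate[ix] if imat.degenerate is not None else None,
    )
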