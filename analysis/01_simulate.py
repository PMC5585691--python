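"""Generate the synthetic study: a linked fecal time series and biopsy table.

Emulates the study design — 139 daily fecal samples plus triplicate
biopsies at 7 GI sites over one shared taxon set — with full niche
coupling (competing pairs share a spatial niche), and writes counts,
metadata, taxonomy and the ground truth under results/data/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gutlink.io import CountTable, SampleMetadata, write_count_table, write_metadata, write_taxonomy
from gutlink.simulate import SimulationConfig, simulate_paired_study

SEED = 11
OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(niche_coupling=1.0, seed=SEED)
    bundle = simulate_paired_study(cfg)

    write_count_table(bundle["counts_fecal"], OUT / "fecal_counts.tsv")
    write_metadata(bundle["meta_fecal"], OUT / "fecal_metadata.tsv")
    write_count_table(bundle["counts_biopsy"], OUT / "biopsy_counts.tsv")
    write_metadata(bundle["meta_biopsy"], OUT / "biopsy_metadata.tsv")
    write_taxonomy(bundle["taxonomy"], OUT / "taxonomy.tsv")
    np.savetxt(OUT / "beta_true.tsv", bundle["beta_true"], delimiter="\t")
    bundle["spatial_truth"].to_csv(OUT / "spatial_truth.tsv", sep="\t", index=False)
    bundle["pairs"].to_csv(OUT / "interaction_truth.tsv", sep="\t", index=False)

    # combined table + metadata for whole-study stages
    comb = np.hstack([bundle["counts_fecal"].values, bundle["counts_biopsy"].values])
    table = CountTable(
        comb,
        bundle["counts_fecal"].taxa_ids,
        bundle["counts_fecal"].sample_ids + bundle["counts_biopsy"].sample_ids,
    )
    meta = SampleMetadata(
        pd.concat(
            [bundle["meta_fecal"].frame, bundle["meta_biopsy"].frame]
        ).reset_index(drop=True)
    )
    write_count_table(table, OUT / "combined_counts.tsv")
    write_metadata(meta, OUT / "combined_metadata.tsv")

    summary = {
        "seed": SEED,
        "n_taxa": cfg.n_taxa,
        "n_fecal_days": cfg.n_days,
        "n_biopsy_samples": bundle["counts_biopsy"].n_samples,
        "n_interacting_pairs": int(len(bundle["pairs"])),
        "interaction_categories": bundle["pairs"]["category"].value_counts().to_dict(),
    }
    (OUT / "simulation_summary.json").write_text(json.dumps(summary, indent=2))
    print("simulated study written to", OUT)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
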