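"""Alpha diversity along the GI tract, Bray-Curtis ordination, and ANOSIM.

Computes per-sample Shannon/richness/evenness on the common-scaled,
singleton-removed table, tests site structuring of the biopsy samples
(ANOSIM, 10,000 permutations), ordinates them by NMDS, and checks the
genus-collapse robustness of the distance structure (Pearson correlation
of OTU-level vs genus-level Bray-Curtis matrices).
"""

import json
from pathlib import Path

import pandas as pd

from gutlink import diversity, prep
from gutlink.io import collapse_to_rank, read_count_table, read_metadata, read_taxonomy

SEED = 11
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    table = read_count_table(ROOT / "data" / "combined_counts.tsv")
    meta = read_metadata(ROOT / "data" / "combined_metadata.tsv")
    taxonomy = read_taxonomy(ROOT / "data" / "taxonomy.tsv")
    scaled = prep.common_scale(prep.remove_singletons(table))

    alpha = diversity.alpha_diversity(scaled)
    alpha = alpha.join(meta.frame[["sample_type", "site", "day"]])
    alpha.to_csv(ROOT / "diversity.tsv", sep="\t")
    by_site = (
        alpha[alpha.sample_type == "biopsy"].groupby("site")["shannon"].agg(["mean", "sem"])
    )
    print("mean Shannon index per biopsy site:")
    print(by_site.round(3))

    biopsy_ids = list(meta.frame.index[meta.frame.sample_type == "biopsy"])
    biopsy = prep.common_scale(table.select_samples(biopsy_ids))
    dist = diversity.bray_curtis(biopsy)
    sites = meta.frame.loc[biopsy.sample_ids, "site"].to_numpy()
    r, p = diversity.anosim(dist, sites, n_perm=10_000, seed=SEED)
    print(f"\nANOSIM on biopsy sites: R = {r:.3f}, p = {p:.4f}")

    coords, stress, _ = diversity.nmds(dist, k=2, seed=SEED)
    nmds_df = pd.DataFrame(coords, index=biopsy.sample_ids, columns=["dim1", "dim2"])
    nmds_df["site"] = sites
    nmds_df.to_csv(ROOT / "nmds_biopsy.tsv", sep="\t")
    print(f"NMDS stress (k=2): {stress:.3f}")

    genus = collapse_to_rank(biopsy, taxonomy, "genus")
    dist_genus = diversity.bray_curtis(genus)
    r_collapse = diversity.matrix_correlation(dist, dist_genus)
    print(f"OTU-level vs genus-level Bray-Curtis correlation: {r_collapse:.3f}")

    (ROOT / "ordination_summary.json").write_text(
        json.dumps(
            {
                "anosim_R": r,
                "anosim_p": p,
                "nmds_stress": stress,
                "genus_collapse_pearson": r_collapse,
            },
            indent=2,
        )
    )


if __name__ == "__main__":
    main()
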