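"""Spearman and SparCC cooccurrence matrices, temporal and spatial.

Temporal matrices come from the consistency-filtered daily fecal series;
spatial matrices from the biopsy samples of the same taxa (Spearman over
the 7 per-site mean profiles; SparCC on the raw biopsy counts).
"""

from pathlib import Path

import pandas as pd

from gutlink import cooccur, prep
from gutlink.io import read_count_table, read_metadata

SEED = 11
ROOT = Path(__file__).resolve().parents[1] / "results"


def save(corr, name):
    pd.DataFrame(corr.matrix, index=corr.taxa_ids, columns=corr.taxa_ids).to_csv(
        ROOT / name, sep="\t"
    )


def main() -> None:
    fecal_raw = read_count_table(ROOT / "data" / "fecal_counts.tsv")
    fecal_meta = read_metadata(ROOT / "data" / "fecal_metadata.tsv")
    biopsy_raw = read_count_table(ROOT / "data" / "biopsy_counts.tsv")
    biopsy_meta = read_metadata(ROOT / "data" / "biopsy_metadata.tsv")

    fecal = prep.filter_consistency(prep.common_scale(fecal_raw), 0.0005, 0.9)
    taxa = list(fecal.taxa_ids)
    fecal_raw_f = fecal_raw.select_taxa(taxa)
    biopsy_raw_f = biopsy_raw.select_taxa(taxa)

    t_spear = cooccur.spearman_matrix(fecal, flavor="temporal")
    t_sparcc = cooccur.sparcc_matrix(fecal_raw_f, seed=SEED, flavor="temporal")
    prof = cooccur.spatial_profile_table(biopsy_raw_f, biopsy_meta)
    s_spear = cooccur.spearman_matrix(prof, flavor="spatial")
    s_sparcc = cooccur.sparcc_matrix(biopsy_raw_f, seed=SEED + 1, flavor="spatial")

    for corr, name in [
        (t_spear, "corr_temporal_spearman.tsv"),
        (t_sparcc, "corr_temporal_sparcc.tsv"),
        (s_spear, "corr_spatial_spearman.tsv"),
        (s_sparcc, "corr_spatial_sparcc.tsv"),
    ]:
        save(corr, name)
        import numpy as np

        off = corr.matrix[~np.eye(corr.n, dtype=bool)]
        print(f"{name}: {corr.n} taxa, off-diagonal mean {off.mean():+.3f}, "
              f"range [{off.min():+.2f}, {off.max():+.2f}]")


if __name__ == "__main__":
    main()
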