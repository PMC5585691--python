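"""Library-size normalization and abundance/prevalence filtering.

Common scaling multiplies each sample's counts by (smallest library /
that library), giving every sample the same effective depth; it replaces
rarefying (it is the expectation over infinitely repeated subsamplings).
"""

from __future__ import annotations

import math

import numpy as np

from .io import CountTable


def common_scale(table: CountTable) -> CountTable:
    """Scale every column to the smallest library size."""
    libs = table.library_sizes
    if (libs <= 0).any():
        j = int(np.argmin(libs))
        raise ValueError(f"sample {table.sample_ids[j]!r} has zero library size")
    factors = libs.min() / libs
    return CountTable(
        table.values * factors, list(table.taxa_ids), list(table.sample_ids)
    )


def remove_singletons(table: CountTable) -> CountTable:
    """Drop OTUs with total count ≤ 1 across all samples (applied to raw counts)."""
    keep = table.values.sum(axis=1) > 1
    return table.select_taxa(keep)


def _qualifying_samples(table: CountTable, min_rel_abund: float) -> np.ndarray:
    """Per-OTU count of samples where the OTU meets the abundance threshold.

    The per-sample read threshold is ceil(min_rel_abund × library size), so on
    a common-scaled table the fraction maps to a single integer read cutoff
    (e.g. 0.1% of a 10,662-read common library → 11 reads).
    """
    thresholds = np.array(
        [math.ceil(min_rel_abund * lib) for lib in table.library_sizes]
    )
    return (table.values >= np.maximum(thresholds, 1e-12)).sum(axis=1)


def filter_prevalence(
    table: CountTable, min_rel_abund: float, min_samples: int
) -> CountTable:
    """Keep OTUs at ≥ `min_rel_abund` relative abundance in ≥ `min_samples` samples."""
    if min_samples > table.n_samples:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {table.n_samples} samples present"
        )
    keep = _qualifying_samples(table, min_rel_abund) >= min_samples
    return table.select_taxa(keep)


def filter_consistency(
    table: CountTable, min_rel_abund: float, min_sample_fraction: float
) -> CountTable:
    """Keep OTUs at ≥ `min_rel_abund` in at least a fraction of all samples.

    "At least 90% of samples" is a lower bound, so the sample requirement is
    the ceiling of fraction × n_samples (and never less than one sample).
    """
    if not 0 <= min_sample_fraction <= 1:
        raise ValueError("min_sample_fraction must be in [0, 1]")
    required = max(1, math.ceil(min_sample_fraction * table.n_samples))
    keep = _qualifying_samples(table, min_rel_abund) >= required
    return table.select_taxa(keep)
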