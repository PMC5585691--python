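"""Shared data model and flat-file I/O for OTU count tables.

The canonical on-disk format is tab-separated text: count tables are
taxa-as-rows with a header row of sample ids and a first column ``otu_id``;
metadata and taxonomy tables are plain TSV with one row per sample / OTU.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: GI biopsy sites ordered proximal (terminal ileum) to distal (rectum).
SITES = ("TI", "IV", "AC", "TC", "DC", "SC", "R")

#: Approximate distance of each biopsy site from the anus, in cm.
SITE_DISTANCE_CM = {
    "TI": 155.0,
    "IV": 150.0,
    "AC": 142.0,
    "TC": 109.0,
    "DC": 64.0,
    "SC": 20.0,
    "R": 10.0,
}

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class ParseError(ValueError):
    """Raised when an input table violates the format contract."""


@dataclass
class CountTable:
    """Taxa-by-samples abundance matrix.

    Raw counts are integers; common-scaled counts may be fractional.
    ``library_sizes`` always equal the column sums.
    """

    values: np.ndarray
    taxa_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.taxa_ids = [str(t) for t in self.taxa_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ParseError("count matrix must be 2-dimensional")
        if self.values.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise ParseError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.taxa_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ParseError("count matrix contains non-finite values")
        if (self.values < 0).any():
            bad = np.argwhere(self.values < 0)[0]
            raise ParseError(
                f"negative value at taxon {self.taxa_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        for name, ids in (("taxon", self.taxa_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ParseError(f"duplicated {name} id {i!r}")
                seen.add(i)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def library_sizes(self) -> np.ndarray:
        """Per-sample column sums."""
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa_ids, columns=self.sample_ids)

    def select_taxa(self, keep: np.ndarray | list) -> "CountTable":
        """Row-subset by boolean mask or list of taxon ids."""
        if isinstance(keep, (list, tuple)) and keep and isinstance(keep[0], str):
            idx = [self.taxa_ids.index(t) for t in keep]
        else:
            idx = np.flatnonzero(np.asarray(keep))
        return CountTable(
            self.values[idx, :],
            [self.taxa_ids[i] for i in idx],
            list(self.sample_ids),
        )

    def select_samples(self, keep: list[str]) -> "CountTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return CountTable(self.values[:, idx], list(self.taxa_ids), list(keep))

    def relative_abundance(self) -> np.ndarray:
        """Per-sample relative abundances (columns sum to 1)."""
        libs = self.library_sizes
        if (libs == 0).any():
            j = int(np.argmin(libs))
            raise ValueError(f"sample {self.sample_ids[j]!r} has zero total count")
        return self.values / libs


@dataclass
class SampleMetadata:
    """Per-sample annotations: type (fecal/biopsy), day, site, replicate, distance."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "sample_type")
    OPTIONAL = ("day", "site", "replicate", "distance_cm")

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ParseError(f"metadata missing required column {col!r}")
        for col in self.OPTIONAL:
            if col not in df.columns:
                df[col] = np.nan
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ParseError(f"duplicated sample id {dup!r} in metadata")
        bad_type = ~df["sample_type"].isin(["fecal", "biopsy"])
        if bad_type.any():
            raise ParseError(
                f"unknown sample_type {df.loc[bad_type, 'sample_type'].iloc[0]!r}"
            )
        biopsy = df["sample_type"] == "biopsy"
        if biopsy.any():
            bad_site = biopsy & ~df["site"].isin(SITES)
            if bad_site.any():
                raise ParseError(
                    f"biopsy sample with invalid site "
                    f"{df.loc[bad_site, 'site'].iloc[0]!r}"
                )
            # default anatomical distances for biopsy sites
            missing = biopsy & df["distance_cm"].isna()
            df.loc[missing, "distance_cm"] = df.loc[missing, "site"].map(
                SITE_DISTANCE_CM
            )
        fecal = df["sample_type"] == "fecal"
        if fecal.any() and df.loc[fecal, "day"].isna().any():
            raise ParseError("fecal samples must carry a collection day")
        self.frame = df.set_index("sample_id", drop=False)

    def subset(self, sample_ids: list[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)].reset_index(drop=True))

    def fecal_ids_by_day(self) -> tuple[list[str], np.ndarray]:
        """Fecal sample ids sorted by collection day, with the day vector."""
        fec = self.frame[self.frame["sample_type"] == "fecal"].copy()
        fec["day"] = fec["day"].astype(float)
        if fec["day"].duplicated().any():
            d = fec.loc[fec["day"].duplicated(), "day"].iloc[0]
            raise ValueError(f"duplicate collection day {d:g} among fecal samples")
        fec = fec.sort_values("day")
        return list(fec["sample_id"]), fec["day"].to_numpy(dtype=int)

    def biopsy_layout(self) -> pd.DataFrame:
        """Biopsy rows sorted by site order (TI→R) then replicate."""
        b = self.frame[self.frame["sample_type"] == "biopsy"].copy()
        b["__ord"] = b["site"].map({s: k for k, s in enumerate(SITES)})
        return b.sort_values(["__ord", "replicate"]).drop(columns="__ord")


@dataclass
class TaxonomyTable:
    """OTU → six-rank lineage. Any rank may be unassigned (empty/NaN)."""

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        if "otu_id" not in df.columns:
            raise ParseError("taxonomy missing 'otu_id' column")
        for r in RANKS:
            if r not in df.columns:
                df[r] = np.nan
        df["otu_id"] = df["otu_id"].astype(str)
        if df["otu_id"].duplicated().any():
            dup = df.loc[df["otu_id"].duplicated(), "otu_id"].iloc[0]
            raise ParseError(f"duplicated otu id {dup!r} in taxonomy")
        self.frame = df.set_index("otu_id", drop=False)

    def rank_labels(self, otu_ids: list[str], rank: str) -> list[str]:
        """Label of each OTU at `rank`; missing/unassigned → 'unclassified_<rank>'."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        fallback = f"unclassified_{rank}"
        out = []
        for otu in otu_ids:
            if otu not in self.frame.index:
                logger.warning("OTU %s missing from taxonomy; treated as %s", otu, fallback)
                out.append(fallback)
                continue
            lab = self.frame.at[otu, rank]
            if pd.isna(lab) or str(lab).strip() == "":
                out.append(fallback)
            else:
                out.append(str(lab))
        return out


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path, format: str = "tsv") -> CountTable:
    """Read a taxa-by-samples count table.

    TSV dialect: first column ``otu_id`` (taxa as rows), header row of sample
    ids. Row and column order are preserved.
    """
    if format != "tsv":
        raise ValueError(f"unsupported count-table format {format!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as e:
        raise ParseError(f"empty or headerless count table: {path}") from e
    if df.shape[1] == 0:
        raise ParseError(f"count table {path} has no sample columns")
    if df.columns.str.startswith("Unnamed").any():
        raise ParseError(f"malformed header in {path}: unnamed sample column")
    vals = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(vals).any():
        i, j = np.argwhere(np.isnan(vals))[0]
        raise ParseError(
            f"non-numeric value at row {df.index[i]!r}, column {df.columns[j]!r}"
        )
    return CountTable(vals, list(df.index.astype(str)), list(df.columns.astype(str)))


def write_count_table(table: CountTable, path) -> None:
    df = table.to_frame()
    # keep integer tables integral on disk so round trips are lossless
    if np.allclose(table.values, np.round(table.values)):
        df = df.round().astype(np.int64)
    df.index.name = "otu_id"
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    except pd.errors.EmptyDataError as e:
        raise ParseError(f"empty metadata file: {path}") from e
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.frame.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as e:
        raise ParseError(f"empty taxonomy file: {path}") from e
    return TaxonomyTable(df)


def write_taxonomy(tax: TaxonomyTable, path) -> None:
    tax.frame.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def collapse_to_rank(
    table: CountTable, taxonomy: TaxonomyTable, rank: str
) -> CountTable:
    """Sum OTU counts into distinct labels at a taxonomic rank.

    Unassigned OTUs are pooled into an ``unclassified_<rank>`` bucket rather
    than dropped, so per-sample totals are conserved exactly.
    """
    labels = taxonomy.rank_labels(table.taxa_ids, rank)
    order: list[str] = []
    index: dict[str, int] = {}
    for lab in labels:
        if lab not in index:
            index[lab] = len(order)
            order.append(lab)
    out = np.zeros((len(order), table.n_samples))
    for row, lab in enumerate(labels):
        out[index[lab]] += table.values[row]
    return CountTable(out, order, list(table.sample_ids))
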