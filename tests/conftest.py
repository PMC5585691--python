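import numpy as np
import pandas as pd
import pytest

from gutlink.io import CountTable, SampleMetadata, TaxonomyTable
from gutlink.simulate import SimulationConfig, simulate_paired_study


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]),
        ["OTU1", "OTU2", "OTU3"],
        ["S1", "S2"],
    )


@pytest.fixture
def small_taxonomy() -> TaxonomyTable:
    return TaxonomyTable(
        pd.DataFrame(
            {
                "otu_id": ["OTU1", "OTU2", "OTU3"],
                "kingdom": "Bacteria",
                "phylum": ["P1", "P1", "P2"],
                "class": "C",
                "order": "O",
                "family": "F",
                "genus": ["G1", "G1", "G2"],
            }
        )
    )


@pytest.fixture
def biopsy_metadata() -> SampleMetadata:
    rows = []
    for site in ("TI", "IV", "AC", "TC", "DC", "SC", "R"):
        for rep in (1, 2, 3):
            rows.append(
                {
                    "sample_id": f"B_{site}_{rep}",
                    "sample_type": "biopsy",
                    "site": site,
                    "replicate": rep,
                }
            )
    return SampleMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def paired_coupled():
    """One linked temporal+spatial simulation with full niche coupling."""
    return simulate_paired_study(SimulationConfig(niche_coupling=1.0, seed=11))
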