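import numpy as np
import pandas as pd
import pytest

from estmeio.io import OtuTable
from estmeio import synthio


@pytest.fixture
def tiny_table() -> OtuTable:
    """Hand-built 5-OTU x 4-sample table (2 stations x 2 replicates)."""
    counts = pd.DataFrame(
        {
            "st1_r1": [10, 0, 5, 0, 3],
            "st1_r2": [8, 1, 0, 0, 2],
            "st2_r1": [0, 4, 6, 2, 0],
            "st2_r2": [0, 5, 7, 1, 0],
        },
        index=pd.Index(
            ["otu1", "otu2", "otu3", "otu4", "otu5"], name="otu_id"
        ),
    )
    taxonomy = pd.DataFrame(
        {
            "phylum": ["Nematoda", "Nematoda", "Nematoda", "Annelida",
                       "Alveolata"],
            "family": ["Xyalidae", "Tripylidae", "Chromadoridae",
                       "Nereididae", "NA"],
        },
        index=counts.index,
    )
    samples = pd.DataFrame(
        {
            "station": ["st1", "st1", "st2", "st2"],
            "replicate": [1, 2, 1, 2],
            "estuary": ["thames"] * 4,
        },
        index=pd.Index(counts.columns, name="sample"),
    )
    return OtuTable(counts=counts, taxonomy=taxonomy, samples=samples)


@pytest.fixture
def small_scenario() -> synthio.ScenarioConfig:
    """Fast scenario for pipeline-level tests."""
    return synthio.ScenarioConfig(
        name="mini",
        n_stations=6,
        n_replicates=2,
        channel_length_km=40.0,
        salinity_range_max=12.0,
        taxon_pool={"Nematoda": 40, "Mollusca": 15, "Annelida": 12},
        driver_effects={
            "Nematoda": [("salinity_range", 0.8)],
            "Mollusca": [("salinity_range", -1.0)],
            "Annelida": [("d50", 0.8)],
        },
        reads_per_sample=(500, 2000),
        seed=11,
    )
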