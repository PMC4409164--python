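"""Core data containers and text-format IO.

The analysis operates on three tables:

* an OTU table — OTU × sample read counts with per-OTU taxonomy
  (phylum, family) and per-sample metadata (station, replicate, estuary);
* an environmental matrix — stations × named driver variables;
* distance matrices — handled throughout as :class:`skbio.DistanceMatrix`.

All on-disk formats are plain text: the OTU table is a TSV with OTUs as
rows, samples as columns and a trailing ``taxonomy`` column encoded
``phylum;family``; sample metadata is a separate TSV; environmental
matrices are CSV with the station as index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "read_otu_table",
    "write_otu_table",
    "read_env_matrix",
    "write_env_matrix",
    "ENV_DRIVERS",
]

#: The 14 core environmental driver columns, in canonical order.
ENV_DRIVERS = [
    "spring_tidal_range",
    "mean_velocity",
    "max_velocity",
    "mean_bed_shear_stress",
    "max_bed_shear_stress",
    "d50",
    "d10",
    "pct_clay",
    "pct_silt",
    "pct_fine_sand",
    "pct_medium_sand",
    "pct_coarse_sand",
    "pct_gravel",
    "salinity_range",
]

#: Optional macrofauna ("top-down") columns appended after the core 14.
MACROFAUNA_COLUMNS = [
    "macrofauna_species_richness",
    "macrofauna_abundance",
    "macrofauna_biomass",
]


class OtuTableError(ValueError):
    """Raised for malformed or inconsistent OTU tables."""


@dataclass
class OtuTable:
    """OTU × sample count matrix with taxonomy and sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by OTU id, columns are sample ids, values are
        non-negative integer read counts (or 0/1 for presence tables).
    taxonomy
        DataFrame indexed by OTU id with columns ``phylum`` and
        ``family`` (missing annotations encoded as the string "NA").
    samples
        DataFrame indexed by sample id with columns ``station``,
        ``replicate`` and ``estuary``.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise OtuTableError("negative counts in OTU table")
        missing_tax = self.counts.index.difference(self.taxonomy.index)
        if len(missing_tax):
            raise OtuTableError(
                f"OTUs without taxonomy: {list(missing_tax[:5])}"
            )
        missing_meta = set(self.counts.columns) - set(self.samples.index)
        if missing_meta:
            raise OtuTableError(
                f"samples without metadata: {sorted(missing_meta)[:5]}"
            )
        # align auxiliary tables to the count matrix
        self.taxonomy = self.taxonomy.loc[self.counts.index]
        self.samples = self.samples.loc[list(self.counts.columns)]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def stations(self) -> pd.Index:
        return pd.Index(pd.unique(self.samples["station"]), name="station")

    def filter_phyla(self, phyla: list[str]) -> "OtuTable":
        """Restrict to OTUs whose phylum is in *phyla*."""
        keep = self.taxonomy["phylum"].isin(phyla)
        if not keep.any():
            raise OtuTableError(
                f"no OTUs left after filtering to phyla {phyla!r}"
            )
        return OtuTable(
            counts=self.counts.loc[keep].copy(),
            taxonomy=self.taxonomy.loc[keep].copy(),
            samples=self.samples.copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, OtuTable):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.taxonomy.equals(other.taxonomy)
            and self.samples.equals(other.samples)
        )


def write_otu_table(table: OtuTable, counts_path: str | Path,
                    samples_path: str | Path) -> None:
    """Write an :class:`OtuTable` as two TSV files.

    The counts TSV has one row per OTU, one column per sample and a
    trailing ``taxonomy`` column encoded ``phylum;family``.
    """
    out = table.counts.copy()
    out["taxonomy"] = (
        table.taxonomy["phylum"].astype(str)
        + ";"
        + table.taxonomy["family"].astype(str)
    )
    out.to_csv(counts_path, sep="\t", index_label="otu_id")
    table.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_otu_table(counts_path: str | Path,
                   samples_path: str | Path) -> OtuTable:
    """Read an OTU table written by :func:`write_otu_table`."""
    raw = pd.read_csv(counts_path, sep="\t", index_col="otu_id")
    if "taxonomy" not in raw.columns:
        raise OtuTableError(f"{counts_path}: missing 'taxonomy' column")
    tax_split = []
    for lineno, (otu, tax) in enumerate(raw["taxonomy"].items(), start=2):
        parts = str(tax).split(";")
        if len(parts) != 2:
            raise OtuTableError(
                f"{counts_path}:{lineno}: malformed taxonomy {tax!r} "
                "(expected 'phylum;family')"
            )
        tax_split.append(parts)
    taxonomy = pd.DataFrame(
        tax_split, index=raw.index, columns=["phylum", "family"]
    )
    counts = raw.drop(columns="taxonomy").astype(np.int64)
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    return OtuTable(counts=counts, taxonomy=taxonomy, samples=samples)


def write_env_matrix(env: pd.DataFrame, path: str | Path) -> None:
    env.to_csv(path, index_label="station")


def read_env_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="station")
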