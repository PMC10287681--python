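"""OTU count table container and TSV I/O.

Counts live in a pandas DataFrame (samples x OTUs, non-negative integers);
per-sample habitat labels (the soil origin) and the marker domain
(prokaryote 16S vs fungal ITS) ride along as metadata.  On disk the table is
the field-standard orientation: rows = OTUs, columns = samples, first column
the OTU id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["OtuTable", "read_otu_tsv", "write_otu_tsv"]


@dataclass
class OtuTable:
    counts: pd.DataFrame  # samples x OTUs, integer
    habitat: pd.Series  # per sample, e.g. "natural" / "abandoned"
    domain: str = "prokaryote"  # "prokaryote" | "fungal"
    taxonomy: pd.Series | None = field(default=None)  # per OTU, lineage string

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise DataError("duplicate sample ids")
        if c.columns.has_duplicates:
            raise DataError("duplicate OTU ids")
        arr = c.to_numpy()
        if arr.size and (np.any(arr < 0) or not np.allclose(arr, np.round(arr))):
            raise DataError("counts must be non-negative integers")
        self.counts = c.astype(np.int64)
        self.habitat = pd.Series(self.habitat).reindex(c.index)
        if self.habitat.isna().any():
            raise DataError("habitat label missing for some samples")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def relative(self) -> pd.DataFrame:
        """Per-sample relative abundances (rows sum to 1)."""
        totals = self.sample_totals()
        if (totals == 0).any():
            raise DataError("sample with zero total reads")
        return self.counts.div(totals, axis=0)

    def subset_otus(self, otu_ids) -> "OtuTable":
        tax = self.taxonomy.loc[otu_ids] if self.taxonomy is not None else None
        return OtuTable(self.counts[list(otu_ids)], self.habitat, self.domain, tax)

    def subset_samples(self, sample_ids) -> "OtuTable":
        return OtuTable(
            self.counts.loc[list(sample_ids)],
            self.habitat.loc[list(sample_ids)],
            self.domain,
            self.taxonomy,
        )


def read_otu_tsv(
    path,
    habitat: pd.Series | dict,
    domain: str = "prokaryote",
    taxonomy_path=None,
) -> OtuTable:
    """Read an OTU TSV (rows = OTUs, columns = samples, first column id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    tax = None
    if taxonomy_path is not None:
        tdf = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        tax = tdf.iloc[:, 0]
    return OtuTable(df.T, pd.Series(habitat), domain, tax)


def write_otu_tsv(table: OtuTable, path) -> None:
    out = table.counts.T
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")
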