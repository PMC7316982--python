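"""In-memory containers shared by all pipeline stages.

The lingua franca is the feature-by-sample :class:`AbundanceTable`; gene-level
stages additionally carry a :class:`GeneCatalog` (lengths + depths) and a gene
annotation frame with taxonomic hits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPOSITIONAL_LEVELS = {"gene", "genus", "species", "MLG"}

#: columns of a gene annotation frame (one row per annotated gene)
ANNOTATION_COLUMNS = [
    "gene_id",
    "species_hit",
    "genus_hit",
    "dna_identity",
    "protein_identity",
    "query_overlap",
]


@dataclass
class AbundanceTable:
    """Feature-by-sample abundance matrix with case/control labels.

    Parameters
    ----------
    data:
        DataFrame, features in rows, samples in columns, nonnegative.
    groups:
        Series indexed by sample id with values ``"case"`` / ``"control"``.
    level:
        One of ``gene``, ``genus``, ``species``, ``MLG``, ``metabolite``.
    """

    data: pd.DataFrame
    groups: pd.Series
    level: str = "species"

    def __post_init__(self) -> None:
        if (self.data.values < 0).any():
            raise ValueError("abundances must be nonnegative")
        if self.data.index.has_duplicates or self.data.columns.has_duplicates:
            raise ValueError("feature and sample ids must be unique")
        missing = set(self.data.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)[:5]}")
        self.groups = self.groups.loc[self.data.columns]

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    def group_columns(self, label: str) -> pd.DataFrame:
        return self.data.loc[:, self.groups[self.groups == label].index]

    def is_compositional(self) -> bool:
        return self.level in COMPOSITIONAL_LEVELS

    def closed(self) -> "AbundanceTable":
        """Renormalize each sample (column) to sum to 1."""
        sums = self.data.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("cannot close a table with an all-zero sample")
        return AbundanceTable(self.data / sums, self.groups, self.level)


@dataclass
class GeneCatalog:
    """Per-gene length and length-normalized depth across samples."""

    lengths: pd.Series  # bp, indexed by gene id
    depth: pd.DataFrame  # gene-by-sample, length-normalized
    true_cluster_id: pd.Series | None = None  # planted truth (synthetic only)

    def __post_init__(self) -> None:
        if (self.lengths < 100).any():
            raise ValueError("gene lengths must be >= 100 bp")
        if (self.depth.values < 0).any():
            raise ValueError("depth must be nonnegative")
        if not self.lengths.index.equals(self.depth.index):
            self.lengths = self.lengths.loc[self.depth.index]

    @property
    def gene_ids(self) -> pd.Index:
        return self.depth.index


@dataclass
class MetabolitePanel:
    """Metabolite-by-sample serum concentrations (arbitrary units)."""

    concentrations: pd.DataFrame
    classes: pd.Series  # amino_acid / fatty_acid per metabolite
    linked_species: pd.Series | None = None  # planted driver (synthetic only)

    def __post_init__(self) -> None:
        if (self.concentrations.values < 0).any():
            raise ValueError("concentrations must be nonnegative")

    @property
    def metabolite_ids(self) -> pd.Index:
        return self.concentrations.index


@dataclass
class MLG:
    """Metagenomic linkage group: a cluster of >50 co-abundant genes."""

    mlg_id: str
    member_genes: list[str]
    abundance: pd.Series | None = None  # per-sample, length-weighted mean depth
    taxonomy_level: str = "unclassified"  # species / genus / unclassified
    taxonomy_name: str | None = None

    def __post_init__(self) -> None:
        if self.taxonomy_level == "unclassified" and self.taxonomy_name is not None:
            raise ValueError("unclassified MLG cannot carry a taxonomy name")
        if self.taxonomy_level != "unclassified" and self.taxonomy_name is None:
            raise ValueError("classified MLG requires a taxonomy name")

    @property
    def size(self) -> int:
        return len(self.member_genes)


def mouse_outcome_frame(records: list[dict]) -> pd.DataFrame:
    """Validate and assemble a mouse-outcome table.

    Columns: mouse_id, arm, aneurysm (bool), rupture (bool), onset_day
    (1..21), censored (bool; censored animals carry day 21).
    Rupture implies aneurysm; only symptomatic (event) animals carry an
    onset day < 21.
    """
    df = pd.DataFrame.from_records(records)
    if (df["rupture"] & ~df["aneurysm"]).any():
        raise ValueError("rupture without aneurysm is inconsistent")
    if ((df["onset_day"] < 1) | (df["onset_day"] > 21)).any():
        raise ValueError("onset_day must lie in [1, 21]")
    if (df.loc[df["censored"], "onset_day"] != 21).any():
        raise ValueError("censored animals must carry day 21")
    return df


def as_frame(table) -> pd.DataFrame:
    """Coerce an AbundanceTable, DataFrame, or array to a DataFrame."""
    if isinstance(table, AbundanceTable):
        return table.data
    if isinstance(table, pd.DataFrame):
        return table
    return pd.DataFrame(np.asarray(table, dtype=float))


def close_columns(values: np.ndarray) -> np.ndarray:
    """Normalize columns of a nonnegative matrix to unit sum."""
    sums = values.sum(axis=0, keepdims=True)
    if (sums <= 0).any():
        raise ValueError("all-zero sample cannot be closed")
    return values / sums
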