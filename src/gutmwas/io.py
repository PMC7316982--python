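"""Flat-file (TSV/JSON) handoff between pipeline stages.

Abundance tables are written features-in-rows, samples-in-columns, first
column = feature id; metadata, annotations, mouse outcomes and result
tables are plain TSV so every intermediate is inspectable and any stage can
be re-run from its persisted inputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gutmwas.containers import AbundanceTable, GeneCatalog, MetabolitePanel


def write_table(table: AbundanceTable, path) -> None:
    df = table.data.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def write_metadata(groups: pd.Series, path) -> None:
    df = groups.rename("group").to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_table(path, metadata_path, level: str = "species") -> AbundanceTable:
    data = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return AbundanceTable(data=data, groups=meta["group"], level=level)


def write_catalog(catalog: GeneCatalog, depth_path, lengths_path) -> None:
    df = catalog.depth.copy()
    df.index.name = "gene_id"
    df.to_csv(depth_path, sep="\t")
    ldf = catalog.lengths.rename("length").to_frame()
    if catalog.true_cluster_id is not None:
        ldf["true_cluster_id"] = catalog.true_cluster_id
    ldf.index.name = "gene_id"
    ldf.to_csv(lengths_path, sep="\t")


def read_catalog(depth_path, lengths_path) -> GeneCatalog:
    depth = pd.read_csv(depth_path, sep="\t", index_col=0)
    meta = pd.read_csv(lengths_path, sep="\t", index_col=0)
    truth = meta["true_cluster_id"] if "true_cluster_id" in meta else None
    return GeneCatalog(lengths=meta["length"], depth=depth, true_cluster_id=truth)


def write_metabolites(panel: MetabolitePanel, conc_path, meta_path) -> None:
    df = panel.concentrations.copy()
    df.index.name = "metabolite_id"
    df.to_csv(conc_path, sep="\t")
    meta = panel.classes.rename("class").to_frame()
    if panel.linked_species is not None:
        meta["linked_species"] = panel.linked_species
    meta.index.name = "metabolite_id"
    meta.to_csv(meta_path, sep="\t")


def read_metabolites(conc_path, meta_path) -> MetabolitePanel:
    conc = pd.read_csv(conc_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    linked = meta["linked_species"] if "linked_species" in meta else None
    return MetabolitePanel(concentrations=conc, classes=meta["class"], linked_species=linked)


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
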