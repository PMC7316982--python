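"""Metagenomic linkage group (MLG) construction.

Differentially abundant marker genes are clustered by their co-abundance
across samples (canopy/centroid clustering on log-transformed depth,
Pearson >= 0.9 by default, the co-abundance-gene-group lineage); clusters
with more than 50 genes become MLGs. MLG abundance is the gene-length
weighted mean of member depths, and taxonomy is voted from per-gene
annotation hits:

* species: >= 90% of members hit one species with DNA identity >= 95% and
  query overlap >= 70%;
* else genus: >= 80% of members hit one genus with DNA and protein identity
  both >= 85%;
* else unclassified.

All percentage thresholds are inclusive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gutmwas.containers import MLG, GeneCatalog


def _log_profiles(depth: pd.DataFrame) -> np.ndarray:
    """Log-transform with pseudocount = half the smallest nonzero depth."""
    values = depth.values
    nonzero = values[values > 0]
    pseudo = 0.5 * nonzero.min() if nonzero.size else 1e-9
    return np.log(values + pseudo)


def _corr_to_centroid(X: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    cc = centroid - centroid.mean()
    denom = np.sqrt((Xc**2).sum(axis=1) * (cc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ cc) / denom
    return np.where(denom > 0, r, 0.0)


def cluster_marker_genes(
    catalog: GeneCatalog,
    marker_ids,
    corr_threshold: float = 0.9,
    min_size: int = 51,
    max_iter: int = 50,
) -> list[MLG]:
    """Canopy-cluster marker genes on their log-abundance correlation.

    Iterates over unassigned genes in the given marker order: each seeds a
    canopy that absorbs genes whose Pearson correlation to the running
    centroid reaches ``corr_threshold``, recomputing the centroid until
    membership converges. Canopies whose centroids correlate at or above the
    threshold are then merged. Only clusters with ``size >= min_size``
    (strictly more than 50 genes by default) are returned, as
    taxonomy-less :class:`MLG` objects.
    """
    if not 0.0 < corr_threshold < 1.0:
        raise ValueError("corr_threshold must lie in (0, 1)")
    marker_ids = [g for g in marker_ids if g in set(catalog.gene_ids)]
    if len(marker_ids) < min_size:
        return []
    depth = catalog.depth.loc[marker_ids]
    X = _log_profiles(depth)
    n = len(marker_ids)

    assigned = np.zeros(n, dtype=bool)
    canopies: list[np.ndarray] = []  # boolean member masks
    for seed in range(n):
        if assigned[seed]:
            continue
        members = np.zeros(n, dtype=bool)
        members[seed] = True
        for _ in range(max_iter):
            centroid = X[members].mean(axis=0)
            corr = _corr_to_centroid(X, centroid)
            new_members = (~assigned) & (corr >= corr_threshold)
            new_members[seed] = True
            if (new_members == members).all():
                break
            members = new_members
        assigned |= members
        canopies.append(members)

    # merge canopies whose centroids correlate at or above the threshold
    merged = True
    while merged and len(canopies) > 1:
        merged = False
        centroids = np.array([X[m].mean(axis=0) for m in canopies])
        C = np.corrcoef(centroids)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] >= corr_threshold:
            a, b = sorted((i, j))
            canopies[a] = canopies[a] | canopies[b]
            del canopies[b]
            merged = True

    ids = np.array(marker_ids)
    mlgs = []
    k = 0
    for members in canopies:
        if members.sum() >= min_size:
            mlgs.append(
                MLG(mlg_id=f"MLG_{k:04d}", member_genes=list(ids[members]))
            )
            k += 1
    return mlgs


def mlg_abundance(mlg: MLG, catalog: GeneCatalog) -> pd.Series:
    """Gene-length weighted mean of member depths per sample.

    ``a_s = sum_g L_g * depth_{g,s} / sum_g L_g``.
    """
    if not mlg.member_genes:
        raise ValueError("MLG has no member genes")
    missing = set(mlg.member_genes) - set(catalog.gene_ids)
    if missing:
        raise ValueError(f"member genes missing from catalog: {sorted(missing)[:5]}")
    L = catalog.lengths.loc[mlg.member_genes].values.astype(float)
    D = catalog.depth.loc[mlg.member_genes].values
    ab = (L[:, None] * D).sum(axis=0) / L.sum()
    return pd.Series(ab, index=catalog.depth.columns, name=mlg.mlg_id)


def assign_taxonomy(
    mlg: MLG,
    annotations: pd.DataFrame,
    species_frac: float = 0.90,
    species_identity: float = 95.0,
    species_overlap: float = 0.70,
    genus_frac: float = 0.80,
    genus_identity: float = 85.0,
) -> tuple[str, str | None]:
    """Vote the MLG's taxonomy from member-gene annotation hits.

    Missing annotation counts as a non-qualifying gene. Ties between
    candidate names break by higher qualifying fraction, then lexicographic
    name. Returns ``(level, name)`` with level in
    {species, genus, unclassified}.
    """
    members = set(mlg.member_genes)
    size = len(members)
    ann = annotations[annotations["gene_id"].isin(members)]

    sp_ok = ann[
        (ann["dna_identity"] >= species_identity)
        & (ann["query_overlap"] >= species_overlap)
        & ann["species_hit"].notna()
    ]
    if len(sp_ok):
        fracs = sp_ok.groupby("species_hit")["gene_id"].nunique() / size
        fracs = fracs.sort_index().sort_values(ascending=False, kind="mergesort")
        if fracs.iloc[0] >= species_frac:
            return "species", str(fracs.index[0])

    gn_ok = ann[
        (ann["dna_identity"] >= genus_identity)
        & (ann["protein_identity"] >= genus_identity)
        & ann["genus_hit"].notna()
    ]
    if len(gn_ok):
        fracs = gn_ok.groupby("genus_hit")["gene_id"].nunique() / size
        fracs = fracs.sort_index().sort_values(ascending=False, kind="mergesort")
        if fracs.iloc[0] >= genus_frac:
            return "genus", str(fracs.index[0])

    return "unclassified", None


def build_mlgs(
    catalog: GeneCatalog,
    marker_ids,
    annotations: pd.DataFrame,
    corr_threshold: float = 0.9,
    min_size: int = 51,
) -> list[MLG]:
    """Cluster markers, attach abundance, and vote taxonomy in one pass."""
    mlgs = cluster_marker_genes(catalog, marker_ids, corr_threshold, min_size)
    for mlg in mlgs:
        mlg.abundance = mlg_abundance(mlg, catalog)
        level, name = assign_taxonomy(mlg, annotations)
        mlg.taxonomy_level = level
        mlg.taxonomy_name = name
    return mlgs


def mlg_table(mlgs: list[MLG]) -> pd.DataFrame:
    """Stack MLG abundance vectors into an MLG-by-sample DataFrame."""
    if not mlgs:
        return pd.DataFrame()
    return pd.DataFrame({m.mlg_id: m.abundance for m in mlgs}).T
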