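"""Seeded synthetic-cohort generator with planted ground truth.

Emulates a two-group (case/control) shotgun-metagenomic study: a gene
catalog with planted co-abundant clusters, compositional taxon tables with
planted differential taxa, a serum metabolite panel with planted
species-metabolite correlations, and a mouse experiment with per-arm
aneurysm/rupture probabilities. Every output is a deterministic function of
(design, seed); planted truth is returned alongside the data, never inside
it.

Abundances follow a log-normal base signal — the standard heavy-tailed
stand-in for metagenomic depth — and compositional tables are closed
per sample (columns sum to 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gutmwas.containers import (
    AbundanceTable,
    GeneCatalog,
    MetabolitePanel,
    close_columns,
    mouse_outcome_frame,
)

# per-stage substreams derived from the single global seed, so each stage can
# be regenerated independently
_STAGE_OFFSETS = {"genes": 1, "taxa": 2, "metabolites": 3, "mice": 4}


def _rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STAGE_OFFSETS[stage], int(extra)])
    )


@dataclass
class CohortDesign:
    """Parameters of the synthetic case-control cohort.

    Defaults emulate the first study cohort: 100 cases + 100 controls,
    ~10 planted gene clusters large enough to qualify as MLGs, planted
    differential effects of 2 on the log2 scale, and a moderate
    species-metabolite coupling.
    """

    n_per_group: int = 100
    n_genes: int = 1500
    n_clusters: int = 10
    cluster_size_range: tuple[int, int] = (55, 80)
    frac_differential_clusters: float = 0.5
    effect_log2fc: float = 2.0
    noise_sd: float = 0.3
    n_species: int = 50
    n_metabolites: int = 19
    n_differential_taxa: int = 5
    n_linked_metabolites: int = 5
    target_rho: float = 0.6
    annotated_fraction: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_per_group",
            "n_genes",
            "n_clusters",
            "n_species",
            "n_metabolites",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.frac_differential_clusters <= 1.0:
            raise ValueError("frac_differential_clusters must lie in [0, 1]")
        if not 0.0 <= self.annotated_fraction <= 1.0:
            raise ValueError("annotated_fraction must lie in [0, 1]")
        if not -1.0 < self.target_rho < 1.0:
            raise ValueError("target_rho must lie in (-1, 1)")
        lo, hi = self.cluster_size_range
        if not (0 < lo <= hi):
            raise ValueError("cluster_size_range must satisfy 0 < min <= max")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_per_group

    def sample_ids(self) -> list[str]:
        return [f"case_{i:03d}" for i in range(self.n_per_group)] + [
            f"ctrl_{i:03d}" for i in range(self.n_per_group)
        ]

    def group_labels(self) -> pd.Series:
        labels = ["case"] * self.n_per_group + ["control"] * self.n_per_group
        return pd.Series(labels, index=self.sample_ids(), name="group")


def simulate_gene_catalog(
    design: CohortDesign,
) -> tuple[GeneCatalog, pd.DataFrame, pd.DataFrame]:
    """Simulate a gene catalog with planted co-abundant clusters.

    Each cluster shares a log-normal base trajectory across samples; a member
    gene's depth is the base times ``exp(Normal(0, noise_sd))`` gene-specific
    noise. A ``frac_differential_clusters`` subset of clusters shifts the
    case-group mean by ``effect_log2fc`` (log2 scale). Genes not assigned to
    any cluster are independent background. Annotations place
    ``annotated_fraction`` of each cluster's genes on the cluster's true
    species with identities ~95-99% and query overlap ~0.7-1.0; background
    genes receive sub-threshold decoy hits.

    Returns
    -------
    (catalog, annotations, truth)
        ``truth`` has one row per cluster: cluster_id, species, genus,
        size, differential (bool), direction.
    """
    rng = _rng(design.seed, "genes")
    lo, hi = design.cluster_size_range
    sizes = rng.integers(lo, hi + 1, size=design.n_clusters)
    if sizes.sum() > design.n_genes:
        raise ValueError(
            f"clusters need {sizes.sum()} genes but n_genes={design.n_genes}"
        )

    n = design.n_samples
    n_case = design.n_per_group
    gene_ids = [f"gene_{i:05d}" for i in range(design.n_genes)]
    depth = np.empty((design.n_genes, n))
    cluster_of = np.full(design.n_genes, -1)

    n_diff = int(round(design.frac_differential_clusters * design.n_clusters))
    diff_clusters = set(range(n_diff))  # first n_diff clusters carry the effect
    directions = {c: (1 if c % 2 == 0 else -1) for c in diff_clusters}

    pos = 0
    truth_rows = []
    for c, size in enumerate(sizes):
        # shared log-normal base trajectory over samples
        base_log = rng.normal(loc=rng.normal(0.0, 1.0), scale=1.0, size=n)
        if c in diff_clusters:
            shift = directions[c] * design.effect_log2fc * np.log(2.0)
            base_log[:n_case] += shift
        noise = rng.normal(0.0, design.noise_sd, size=(size, n))
        depth[pos : pos + size] = np.exp(base_log[None, :] + noise)
        cluster_of[pos : pos + size] = c
        truth_rows.append(
            {
                "cluster_id": c,
                "species": f"Species_{c:02d}",
                "genus": f"Genus_{c % max(1, design.n_clusters // 2):02d}",
                "size": int(size),
                "differential": c in diff_clusters,
                "direction": (
                    "case_enriched"
                    if directions.get(c, 0) > 0
                    else "control_enriched" if c in diff_clusters else "none"
                ),
            }
        )
        pos += size

    n_bg = design.n_genes - pos
    depth[pos:] = np.exp(rng.normal(0.0, 1.0, size=(n_bg, n)))

    lengths = rng.integers(100, 3000, size=design.n_genes)
    samples = design.sample_ids()
    catalog = GeneCatalog(
        lengths=pd.Series(lengths, index=gene_ids, name="length"),
        depth=pd.DataFrame(depth, index=gene_ids, columns=samples),
        true_cluster_id=pd.Series(cluster_of, index=gene_ids, name="true_cluster_id"),
    )

    truth = pd.DataFrame(truth_rows)
    ann_rows = []
    for gi, gene in enumerate(gene_ids):
        c = cluster_of[gi]
        if c >= 0 and rng.random() < design.annotated_fraction:
            ann_rows.append(
                {
                    "gene_id": gene,
                    "species_hit": truth.loc[c, "species"],
                    "genus_hit": truth.loc[c, "genus"],
                    "dna_identity": rng.uniform(95.0, 99.0),
                    "protein_identity": rng.uniform(86.0, 99.0),
                    "query_overlap": rng.uniform(0.7, 1.0),
                }
            )
        elif c < 0 and rng.random() < 0.5:
            # decoy: hits a random species below the voting thresholds
            ann_rows.append(
                {
                    "gene_id": gene,
                    "species_hit": f"Species_{rng.integers(design.n_clusters):02d}",
                    "genus_hit": f"Genus_{rng.integers(max(1, design.n_clusters // 2)):02d}",
                    "dna_identity": rng.uniform(75.0, 94.0),
                    "protein_identity": rng.uniform(60.0, 84.0),
                    "query_overlap": rng.uniform(0.3, 0.65),
                }
            )
    annotations = pd.DataFrame(
        ann_rows,
        columns=[
            "gene_id",
            "species_hit",
            "genus_hit",
            "dna_identity",
            "protein_identity",
            "query_overlap",
        ],
    )
    return catalog, annotations, truth


def simulate_taxon_table(
    design: CohortDesign, level: str = "species"
) -> tuple[AbundanceTable, pd.DataFrame]:
    """Simulate a compositional taxon table with planted differential taxa.

    Log-normal taxon abundances, ``n_differential_taxa`` taxa shifted in the
    case group by ``effect_log2fc`` (alternating direction), each sample then
    closed to unit sum.

    Returns (table, truth) where truth lists taxon, log2fc and direction.
    """
    if level not in {"species", "genus"}:
        raise ValueError("level must be 'species' or 'genus'")
    if design.n_species < 2:
        raise ValueError("need at least 2 taxa")
    rng = _rng(design.seed, "taxa", extra=0 if level == "species" else 1)

    n = design.n_samples
    n_case = design.n_per_group
    n_taxa = design.n_species
    prefix = "s" if level == "species" else "g"
    taxa = [f"{prefix}__taxon_{i:03d}" for i in range(n_taxa)]

    # taxon-specific location gives the heavy-tailed rank-abundance profile
    loc = rng.normal(0.0, 1.5, size=n_taxa)
    log_abund = loc[:, None] + rng.normal(0.0, 1.0, size=(n_taxa, n))

    n_diff = min(design.n_differential_taxa, n_taxa)
    diff_idx = rng.choice(n_taxa, size=n_diff, replace=False)
    truth_rows = []
    for k, ti in enumerate(diff_idx):
        direction = 1 if k % 2 == 0 else -1
        log_abund[ti, :n_case] += direction * design.effect_log2fc * np.log(2.0)
        truth_rows.append(
            {
                "taxon": taxa[ti],
                "log2fc": direction * design.effect_log2fc,
                "direction": "case_enriched" if direction > 0 else "control_enriched",
            }
        )

    values = close_columns(np.exp(log_abund))
    table = AbundanceTable(
        data=pd.DataFrame(values, index=taxa, columns=design.sample_ids()),
        groups=design.group_labels(),
        level=level,
    )
    return table, pd.DataFrame(truth_rows, columns=["taxon", "log2fc", "direction"])


def simulate_metabolites(
    design: CohortDesign, species: AbundanceTable
) -> MetabolitePanel:
    """Simulate a serum metabolite panel coupled to species abundances.

    Each linked metabolite is a monotone (exponential) transform of a latent
    Gaussian correlated with its driver species' log-abundance. The latent
    correlation is calibrated through the Gaussian-copula identity
    ``rho_spearman = (6/pi) * arcsin(r/2)`` so the empirical Spearman
    correlation comes out near ``target_rho``. Unlinked metabolites are
    independent log-normal noise.
    """
    if species.data.shape[0] < 1:
        raise ValueError("species table must contain at least one taxon")
    rng = _rng(design.seed, "metabolites")
    n = species.data.shape[1]
    n_met = design.n_metabolites
    met_ids = [f"met_{i:02d}" for i in range(n_met)]
    classes = pd.Series(
        ["amino_acid" if i % 3 else "fatty_acid" for i in range(n_met)],
        index=met_ids,
        name="class",
    )

    n_linked = 0 if design.target_rho == 0 else min(design.n_linked_metabolites, n_met)
    n_sp = species.data.shape[0]
    drivers = rng.choice(n_sp, size=n_linked, replace=n_linked > n_sp)

    # latent Pearson correlation giving the requested Spearman under the copula
    r = 2.0 * np.sin(np.pi * design.target_rho / 6.0)

    conc = np.empty((n_met, n))
    linked = pd.Series([None] * n_met, index=met_ids, dtype=object, name="linked_species")
    for m in range(n_met):
        if m < n_linked:
            sp_idx = drivers[m]
            x = np.log(species.data.values[sp_idx] + 1e-12)
            z = (x - x.mean()) / max(x.std(), 1e-12)
            latent = r * z + np.sqrt(max(0.0, 1.0 - r**2)) * rng.normal(size=n)
            linked.iloc[m] = species.data.index[sp_idx]
        else:
            latent = rng.normal(size=n)
        conc[m] = np.exp(0.5 * latent + rng.normal(2.0, 0.1))

    return MetabolitePanel(
        concentrations=pd.DataFrame(conc, index=met_ids, columns=species.data.columns),
        classes=classes,
        linked_species=linked if n_linked else None,
    )


def simulate_mouse_experiment(
    arms: list[tuple[str, int, float, float]], seed: int = 0
) -> pd.DataFrame:
    """Simulate per-animal aneurysm/rupture outcomes over a 21-day window.

    Parameters
    ----------
    arms:
        List of ``(label, n, p_aneurysm, p_rupture_given_aneurysm)``.
    seed:
        Seed for the mouse-stage substream.

    Animals develop an aneurysm with probability ``p_aneurysm``; among those,
    rupture occurs with the conditional probability. Symptomatic (ruptured)
    animals draw an onset day from a geometric distribution truncated to
    days 1-21; all other animals are censored at day 21.
    """
    rng = _rng(seed, "mice")
    records = []
    for label, n, p_an, p_rup in arms:
        if not (0.0 <= p_an <= 1.0 and 0.0 <= p_rup <= 1.0):
            raise ValueError("probabilities must lie in [0, 1]")
        if n < 1:
            raise ValueError("each arm needs at least one animal")
        for i in range(n):
            aneurysm = bool(rng.random() < p_an)
            rupture = bool(aneurysm and rng.random() < p_rup)
            if rupture:
                # geometric(p=0.15) truncated to the 21-day observation window
                u = rng.random()
                p_geom = 0.15
                cdf21 = 1.0 - (1.0 - p_geom) ** 21
                day = int(np.ceil(np.log1p(-u * cdf21) / np.log(1.0 - p_geom)))
                day = min(max(day, 1), 21)
                records.append(
                    {
                        "mouse_id": f"{label}_{i:02d}",
                        "arm": label,
                        "aneurysm": True,
                        "rupture": True,
                        "onset_day": day,
                        "censored": False,
                    }
                )
            else:
                records.append(
                    {
                        "mouse_id": f"{label}_{i:02d}",
                        "arm": label,
                        "aneurysm": aneurysm,
                        "rupture": False,
                        "onset_day": 21,
                        "censored": True,
                    }
                )
    return mouse_outcome_frame(records)
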