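import numpy as np
import pandas as pd
import pytest

from gutmwas.containers import MLG, GeneCatalog
from gutmwas.mlg import (
    assign_taxonomy,
    build_mlgs,
    cluster_marker_genes,
    mlg_abundance,
)
from gutmwas.simulate import CohortDesign, simulate_gene_catalog


def _toy_catalog(depths: dict, lengths: dict) -> GeneCatalog:
    depth = pd.DataFrame(depths).T
    depth.columns = [f"s{i}" for i in range(depth.shape[1])]
    return GeneCatalog(lengths=pd.Series(lengths), depth=depth)


class TestClustering:
    def test_two_planted_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        design = CohortDesign(
            n_per_group=50, n_genes=120, n_clusters=2, cluster_size_range=(60, 60),
            noise_sd=0.2, frac_differential_clusters=1.0, seed=5,
        )
        catalog, _, _ = simulate_gene_catalog(design)
        mlgs = cluster_marker_genes(catalog, list(catalog.gene_ids))
        assert len(mlgs) == 2
        pred = pd.Series(-1, index=catalog.gene_ids)
        for k, m in enumerate(mlgs):
            pred[m.member_genes] = k
        assert adjusted_rand_score(catalog.true_cluster_id, pred) >= 0.95

    def test_uncorrelated_genes_form_no_mlg(self):
        rng = np.random.default_rng(0)
        depth = pd.DataFrame(
            np.exp(rng.normal(size=(60, 40))),
            index=[f"g{i}" for i in range(60)],
            columns=[f"s{i}" for i in range(40)],
        )
        catalog = GeneCatalog(
            lengths=pd.Series(500, index=depth.index), depth=depth
        )
        assert cluster_marker_genes(catalog, list(depth.index)) == []

    def test_cluster_of_exactly_fifty_not_reported(self):
        # the size threshold is strict: >50 genes
        design = CohortDesign(
            n_per_group=30, n_genes=50, n_clusters=1, cluster_size_range=(50, 50),
            noise_sd=0.1, seed=3,
        )
        catalog, _, _ = simulate_gene_catalog(design)
        assert cluster_marker_genes(catalog, list(catalog.gene_ids)) == []

    def test_deterministic_partition_across_runs(self, gene_catalog):
        catalog, _, _ = gene_catalog
        markers = list(catalog.gene_ids)
        m1 = cluster_marker_genes(catalog, markers)
        m2 = cluster_marker_genes(catalog, markers)
        assert [m.member_genes for m in m1] == [m.member_genes for m in m2]

    def test_partition_property(self, gene_catalog):
        catalog, _, _ = gene_catalog
        mlgs = cluster_marker_genes(catalog, list(catalog.gene_ids))
        all_members = [g for m in mlgs for g in m.member_genes]
        assert len(all_members) == len(set(all_members))

    def test_too_few_markers_give_empty_result(self, gene_catalog):
        catalog, _, _ = gene_catalog
        assert cluster_marker_genes(catalog, list(catalog.gene_ids)[:10]) == []


class TestAbundance:
    def test_single_member_equals_gene_abundance(self):
        cat = _toy_catalog({"g1": [2.0, 5.0]}, {"g1": 400})
        ab = mlg_abundance(MLG("m", ["g1"]), cat)
        np.testing.assert_allclose(ab.values, [2.0, 5.0])

    def test_equal_lengths_give_plain_mean(self):
        cat = _toy_catalog({"g1": [2.0], "g2": [4.0]}, {"g1": 200, "g2": 200})
        assert mlg_abundance(MLG("m", ["g1", "g2"]), cat).iloc[0] == pytest.approx(3.0)

    def test_length_weighting(self):
        cat = _toy_catalog({"g1": [4.0], "g2": [0.0]}, {"g1": 100, "g2": 300})
        assert mlg_abundance(MLG("m", ["g1", "g2"]), cat).iloc[0] == pytest.approx(1.0)

    def test_linearity_in_member_abundances(self):
        rng = np.random.default_rng(1)
        cat = _toy_catalog(
            {f"g{i}": rng.uniform(size=5) for i in range(4)},
            {f"g{i}": rng.integers(100, 1000) for i in range(4)},
        )
        m = MLG("m", [f"g{i}" for i in range(4)])
        a1 = mlg_abundance(m, cat)
        cat3 = GeneCatalog(lengths=cat.lengths, depth=cat.depth * 3.0)
        np.testing.assert_allclose(mlg_abundance(m, cat3).values, 3.0 * a1.values)

    def test_empty_member_set_raises(self):
        cat = _toy_catalog({"g1": [1.0]}, {"g1": 100})
        with pytest.raises(ValueError):
            mlg_abundance(MLG("m", []), cat)


def _annotation(gene_ids, species, genus, dna, protein, overlap):
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "species_hit": species,
            "genus_hit": genus,
            "dna_identity": dna,
            "protein_identity": protein,
            "query_overlap": overlap,
        }
    )


class TestTaxonomyVoting:
    def test_species_rule_boundary_inclusive(self):
        # exactly 90 of 100 genes qualify at exactly 95% identity / 0.70 overlap
        genes = [f"g{i}" for i in range(100)]
        ann = _annotation(genes[:90], "S", "G", 95.0, 90.0, 0.70)
        level, name = assign_taxonomy(MLG("m", genes), ann)
        assert (level, name) == ("species", "S")

    def test_cascade_to_genus_rule(self):
        # 89 species-qualifying genes (below 90%), 85 genus-qualifying at 85/85
        genes = [f"g{i}" for i in range(100)]
        ann = pd.concat(
            [
                _annotation(genes[:85], "S", "G", 96.0, 85.0, 0.8),
                _annotation(genes[85:89], "S", None, 96.0, 80.0, 0.8),
            ]
        )
        level, name = assign_taxonomy(MLG("m", genes), ann)
        assert (level, name) == ("genus", "G")

    def test_genus_boundary_at_eighty_percent(self):
        genes = [f"g{i}" for i in range(100)]
        ann = _annotation(genes[:80], None, "G", 85.0, 85.0, 0.5)
        assert assign_taxonomy(MLG("m", genes), ann) == ("genus", "G")
        ann79 = _annotation(genes[:79], None, "G", 85.0, 85.0, 0.5)
        assert assign_taxonomy(MLG("m", genes), ann79) == ("unclassified", None)

    def test_no_annotations_unclassified(self):
        ann = _annotation([], [], [], [], [], [])
        assert assign_taxonomy(MLG("m", ["g1", "g2"]), ann) == ("unclassified", None)

    def test_sub_threshold_identity_does_not_qualify(self):
        genes = [f"g{i}" for i in range(10)]
        ann = _annotation(genes, "S", "G", 94.9, 84.9, 0.69)
        assert assign_taxonomy(MLG("m", genes), ann) == ("unclassified", None)

    def test_tie_breaks_lexicographic(self):
        genes = [f"g{i}" for i in range(10)]
        ann = pd.concat(
            [
                _annotation(genes, "B", "ZZ", 96.0, 90.0, 0.9),
                _annotation(genes, "A", "YY", 96.0, 90.0, 0.9),
            ]
        )
        level, name = assign_taxonomy(MLG("m", genes), ann)
        assert (level, name) == ("species", "A")


def test_build_mlgs_end_to_end_assigns_planted_species(gene_catalog):
    catalog, annotations, truth = gene_catalog
    mlgs = build_mlgs(catalog, list(catalog.gene_ids), annotations)
    assert mlgs
    named = {m.taxonomy_name for m in mlgs if m.taxonomy_level == "species"}
    assert named <= set(truth["species"])
    assert len(named) >= 1
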