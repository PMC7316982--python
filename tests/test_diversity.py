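import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from scipy.spatial.distance import pdist, squareform

from gutmwas.diversity import (
    anosim,
    bray_curtis,
    expected_richness,
    pcoa,
    rarefaction_curve,
    shannon_index,
)


class TestRarefaction:
    def test_exhaustive_draw_recovers_full_richness(self):
        counts = np.array([5, 0, 3, 2])
        curve = rarefaction_curve(counts, [10], n_repeats=5, seed=0)
        assert curve[10] == 3.0

    def test_zero_depth_gives_zero_richness(self):
        assert rarefaction_curve([5, 3, 2], [0], n_repeats=5, seed=0)[0] == 0.0

    def test_mean_matches_hypergeometric_closed_form(self):
        counts = np.array([5, 3, 2])
        n_rep = 4000
        curve = rarefaction_curve(counts, [4], n_repeats=n_rep, seed=1)
        exact = expected_richness(counts, 4)
        # per-repeat richness is in {1,2,3}: SE bound from the range
        se = 1.0 / np.sqrt(n_rep)
        assert abs(curve[4] - exact) < 3 * se

    def test_curve_nondecreasing_in_depth(self):
        counts = np.array([50, 20, 10, 5, 1])
        curve = rarefaction_curve(counts, [5, 20, 50, 86], n_repeats=200, seed=2)
        assert (np.diff(curve.values) >= -1e-9).all()

    def test_depth_exceeding_pool_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            rarefaction_curve([2, 1], [4], n_repeats=2, seed=0)


class TestShannon:
    @pytest.mark.parametrize(
        "vec,expected",
        [
            ([1, 1, 1, 1], 2.0),  # uniform over 4
            ([7], 0.0),  # single taxon
            ([0.5, 0.25, 0.25], 1.5),
        ],
    )
    def test_closed_form_values(self, vec, expected):
        assert shannon_index(vec, base=2) == pytest.approx(expected)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            shannon_index([0.0, 0.0])

    def test_natural_log_base_matches_scipy(self):
        from scipy.stats import entropy

        p = np.array([0.2, 0.3, 0.5])
        assert shannon_index(p, base=np.e) == pytest.approx(entropy(p))


class TestBrayCurtis:
    def test_metric_properties_and_known_values(self):
        df = pd.DataFrame(
            {
                "a": [0.5, 0.5, 0.0],
                "b": [0.0, 0.5, 0.5],
                "c": [0.5, 0.5, 0.0],
                "d": [0.0, 0.0, 1.0],
            }
        )
        D = bray_curtis(df)
        assert np.allclose(D.values, D.values.T)
        assert np.allclose(np.diag(D.values), 0.0)
        assert ((D.values >= 0) & (D.values <= 1)).all()
        assert D.loc["a", "b"] == pytest.approx(0.5)
        assert D.loc["a", "c"] == pytest.approx(0.0)  # identical samples
        assert D.loc["a", "d"] == pytest.approx(1.0)  # disjoint supports

    def test_two_all_zero_samples_flagged(self):
        df = pd.DataFrame({"a": [0.0, 0.0], "b": [0.0, 0.0]})
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(df)


class TestPcoa:
    def test_euclidean_round_trip(self):
        pts = np.random.default_rng(0).normal(size=(6, 3))
        D = squareform(pdist(pts))
        res = pcoa(pd.DataFrame(D))
        D2 = squareform(pdist(res.coordinates.values))
        np.testing.assert_allclose(D, D2, atol=1e-8)
        assert (np.diff(res.eigenvalues) <= 1e-9).all()  # descending
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_all_zero_distances_give_zero_coordinates(self):
        res = pcoa(np.zeros((4, 4)))
        assert res.coordinates.shape[1] == 0 or np.allclose(res.coordinates, 0)

    def test_equilateral_triangle_has_equal_eigenvalues(self):
        D = np.ones((3, 3)) - np.eye(3)
        res = pcoa(D)
        pos = res.eigenvalues[res.eigenvalues > 1e-10]
        assert len(pos) == 2
        assert pos[0] == pytest.approx(pos[1])

    def test_asymmetric_input_raises(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(D)

    def test_matches_skbio_reference(self):
        skbio_ordination = pytest.importorskip("skbio.stats.ordination")
        pts = np.random.default_rng(3).normal(size=(8, 4))
        D = squareform(pdist(pts))
        mine = pcoa(D)
        theirs = skbio_ordination.pcoa(D, method="eigh")
        k = mine.coordinates.shape[1]
        np.testing.assert_allclose(
            np.abs(mine.coordinates.values),
            np.abs(theirs.samples.values[:, :k]),
            atol=1e-6,
        )


class TestAnosim:
    @staticmethod
    def _two_clouds():
        D = np.ones((6, 6))
        D[:3, :3] = 0.1
        D[3:, 3:] = 0.1
        np.fill_diagonal(D, 0.0)
        return D, np.array(["x"] * 3 + ["y"] * 3)

    def test_complete_separation_gives_r_one(self):
        D, g = self._two_clouds()
        res = anosim(D, g, n_permutations=99, seed=0)
        assert res.R == pytest.approx(1.0)
        assert 0 < res.p <= 1

    def test_rank_based_r_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        D = squareform(pdist(pts))
        g = np.array(["a"] * 5 + ["b"] * 5)
        r1 = anosim(D, g, n_permutations=49, seed=0).R
        r2 = anosim(D**2, g, n_permutations=49, seed=0).R
        assert r1 == pytest.approx(r2)

    def test_sampled_p_matches_full_enumeration(self):
        # n=6 (3+3): all 6!/(3!3!) = 20 distinct relabelings enumerable
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        pts[:3] += 1.5
        D = squareform(pdist(pts))
        g = np.array(["a"] * 3 + ["b"] * 3)
        from scipy.stats import rankdata

        iu = np.triu_indices(6, k=1)
        R_mat = np.zeros((6, 6))
        R_mat[iu] = rankdata(D[iu])
        R_mat = R_mat + R_mat.T

        def r_stat(labels):
            within = labels[:, None] == labels[None, :]
            ranks, w = R_mat[iu], within[iu]
            return (ranks[~w].mean() - ranks[w].mean()) / (15 / 2.0)

        r_obs = r_stat(g)
        count = total = 0
        for idx in combinations(range(6), 3):
            lab = np.array(["b"] * 6)
            lab[list(idx)] = "a"
            total += 1
            if r_stat(lab) >= r_obs - 1e-12:
                count += 1
        p_exact = count / total
        res = anosim(D, g, n_permutations=1999, seed=0)
        assert abs(res.p - p_exact) < 3 * np.sqrt(p_exact * (1 - p_exact) / 1999) + 1e-3

    def test_matches_skbio_r_statistic(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 3))
        pts[:6] += 0.8
        D = squareform(pdist(pts))
        g = ["a"] * 6 + ["b"] * 6
        mine = anosim(D, np.array(g), n_permutations=99, seed=0)
        theirs = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(D), grouping=g, permutations=0
        )
        assert mine.R == pytest.approx(theirs["test statistic"])

    def test_singleton_group_raises(self):
        D = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ValueError):
            anosim(D, np.array(["a", "a", "b"]), n_permutations=9, seed=0)
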