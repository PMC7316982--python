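from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from gutmwas.preclinical import (
    deg_set_exclusion,
    fisher_exact_2x2,
    group_compare,
    hypergeom_enrichment,
    km_curve,
    logrank_test,
)
from gutmwas.simulate import simulate_mouse_experiment


def _enumeration_fisher(table):
    """Point-probability two-sided Fisher by direct enumeration."""
    a, b = table[0]
    c, d = table[1]
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    probs = {}
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        probs[k] = comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-7))


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[1, 1], [1, 1]], 1.0),
            ([[2, 0], [0, 2]], 1 / 3),
        ],
    )
    def test_small_tables_match_enumeration_values(self, table, expected):
        assert fisher_exact_2x2(table).p == pytest.approx(expected)

    def test_matches_enumeration_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum(axis=1).min() == 0 or t[:, 0].sum() in (0, t.sum()):
                continue
            assert fisher_exact_2x2(t).p == pytest.approx(_enumeration_fisher(t))

    def test_matches_scipy(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(1)
        for _ in range(20):
            t = rng.integers(1, 20, size=(2, 2))
            assert fisher_exact_2x2(t).p == pytest.approx(fisher_exact(t)[1])

    def test_one_sided_alternatives(self):
        t = [[8, 2], [3, 7]]
        assert fisher_exact_2x2(t, "greater").p < fisher_exact_2x2(t, "less").p

    def test_negative_cell_raises(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [1, 1]])


def _mouse_frame(rows):
    return pd.DataFrame(
        rows, columns=["mouse_id", "arm", "aneurysm", "rupture", "onset_day", "censored"]
    )


class TestKaplanMeier:
    def test_no_censoring_steps_down_by_quarters(self):
        rows = [
            (f"m{i}", "a", True, True, day, False)
            for i, day in enumerate([2, 5, 9, 14])
        ]
        c = km_curve(_mouse_frame(rows), "a")
        np.testing.assert_allclose(c.survival, [0.75, 0.5, 0.25, 0.0])
        np.testing.assert_array_equal(c.times, [2, 5, 9, 14])
        np.testing.assert_array_equal(c.at_risk, [4, 3, 2, 1])

    def test_all_censored_curve_stays_at_one(self):
        rows = [(f"m{i}", "a", True, False, 21, True) for i in range(5)]
        c = km_curve(_mouse_frame(rows), "a")
        assert len(c.times) == 0
        assert len(c.censored) == 5

    def test_mixed_censoring_matches_hand_product_limit(self):
        # events at 3 (n=5), 8 (n=3); censored at 5 and 21
        rows = [
            ("m0", "a", True, True, 3, False),
            ("m1", "a", True, False, 5, True),
            ("m2", "a", True, True, 8, False),
            ("m3", "a", True, False, 21, True),
            ("m4", "a", True, False, 21, True),
        ]
        c = km_curve(_mouse_frame(rows), "a")
        np.testing.assert_allclose(c.survival, [4 / 5, 4 / 5 * 2 / 3])

    def test_restricted_to_aneurysm_positive_animals(self):
        rows = [
            ("m0", "a", True, True, 4, False),
            ("m1", "a", False, False, 21, True),  # excluded from the curve
        ]
        c = km_curve(_mouse_frame(rows), "a")
        np.testing.assert_array_equal(c.at_risk, [1])

    def test_survival_nonincreasing_in_unit_interval(self):
        mouse = simulate_mouse_experiment([("a", 40, 0.9, 0.7)], seed=4)
        c = km_curve(mouse, "a")
        assert ((c.survival >= 0) & (c.survival <= 1)).all()
        assert (np.diff(c.survival) <= 1e-12).all()

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        mouse = simulate_mouse_experiment([("a", 30, 0.9, 0.8)], seed=5)
        c = km_curve(mouse, "a")
        sub = mouse[mouse["aneurysm"]]
        kmf = lifelines.KaplanMeierFitter().fit(sub["onset_day"], ~sub["censored"])
        ref = kmf.survival_function_.loc[c.times].values.ravel()
        np.testing.assert_allclose(c.survival, ref)


class TestLogrank:
    def test_identical_event_times_give_null_statistic(self):
        rows = []
        for arm in ("a", "b"):
            rows += [(f"{arm}{i}", arm, True, True, d, False) for i, d in enumerate([3, 7, 12])]
        res = logrank_test(_mouse_frame(rows))
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_small_case_matches_hand_computed_risk_sets(self):
        # arm a events at 1, 2; arm b event at 3: O-E and V by hand
        rows = [
            ("a0", "a", True, True, 1, False),
            ("a1", "a", True, True, 2, False),
            ("a2", "a", True, False, 21, True),
            ("b0", "b", True, True, 3, False),
            ("b1", "b", True, False, 21, True),
            ("b2", "b", True, False, 21, True),
        ]
        res = logrank_test(_mouse_frame(rows), ["a", "b"])
        # t=1: n=6, na=3, e=0.5, v=0.25; t=2: n=5, na=2, e=0.4, v=0.24
        # t=3: n=4, na=1, e=0.25, v=0.1875
        o_minus_e = (1 - 0.5) + (1 - 0.4) + (0 - 0.25)
        v = 0.25 + 0.24 + 0.1875
        assert res.statistic == pytest.approx(o_minus_e**2 / v)

    def test_shift_invariance_of_event_days(self):
        mouse = simulate_mouse_experiment([("a", 20, 0.9, 0.8), ("b", 20, 0.9, 0.4)], seed=6)
        res1 = logrank_test(mouse)
        shifted = mouse.copy()
        shifted["onset_day"] = shifted["onset_day"] + 5
        res2 = logrank_test(shifted)
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_matches_lifelines_multivariate(self):
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        mouse = simulate_mouse_experiment(
            [("a", 25, 0.9, 0.8), ("b", 25, 0.9, 0.3), ("c", 25, 0.9, 0.5)], seed=7
        )
        res = logrank_test(mouse)
        sub = mouse[mouse["aneurysm"]]
        ref = lifelines_stats.multivariate_logrank_test(
            sub["onset_day"], sub["arm"], ~sub["censored"]
        )
        assert res.statistic == pytest.approx(ref.test_statistic)
        assert res.p == pytest.approx(ref.p_value)

    def test_no_events_warns_with_p_one(self):
        rows = [("a0", "a", True, False, 21, True), ("b0", "b", True, False, 21, True)]
        with pytest.warns(UserWarning, match="no events"):
            res = logrank_test(_mouse_frame(rows))
        assert res.p == 1.0


class TestGroupCompare:
    def test_identical_groups_give_null_t(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        g = np.array(["a"] * 3 + ["b"] * 3)
        res = group_compare(v, g, "t_test")
        assert res.statistic == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_mann_whitney_exact_enumeration(self):
        res = group_compare([1, 2, 3, 4], ["a", "a", "b", "b"], "mann_whitney_exact")
        assert res.p == pytest.approx(1 / 3)

    def test_anova_with_bonferroni_posthoc(self):
        rng = np.random.default_rng(8)
        v = np.concatenate([rng.normal(size=10), rng.normal(size=10), rng.normal(3, 1, 10)])
        g = np.repeat(["a", "b", "c"], 10)
        anova, pairwise = group_compare(v, g, "anova_bonferroni")
        assert anova.p < 0.01
        assert pairwise[("a", "b")].p > 0.05
        assert pairwise[("a", "c")].p < 0.01
        assert all(r.p <= 1.0 for r in pairwise.values())

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="variance"):
            group_compare([1, 1, 2, 2], ["a", "a", "b", "b"], "t_test")


class TestEnrichment:
    def test_term_equal_to_universe_gives_p_one(self):
        uni = {f"g{i}" for i in range(10)}
        res = hypergeom_enrichment({"g0", "g1"}, {"T": uni}, uni)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_full_overlap_closed_form(self):
        uni = {f"g{i}" for i in range(10)}
        de = {f"g{i}" for i in range(5)}
        res = hypergeom_enrichment(de, {"T": de}, uni)
        assert res["p"].iloc[0] == pytest.approx(1 / 252)  # C(5,5)C(5,0)/C(10,5)

    def test_matches_enumeration_oracle_on_small_universe(self):
        rng = np.random.default_rng(9)
        uni = list(range(12))
        term = set(rng.choice(uni, size=5, replace=False).tolist())
        de = set(rng.choice(uni, size=4, replace=False).tolist())
        res = hypergeom_enrichment(de, {"T": term}, uni)
        k_obs = len(de & term)
        count = total = 0
        for draw in combinations(uni, len(de)):
            total += 1
            if len(set(draw) & term) >= k_obs:
                count += 1
        assert res["p"].iloc[0] == pytest.approx(count / total)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(set(), {"T": set()}, set())


class TestDegSets:
    def test_paper_scale_exclusion(self):
        a = {f"g{i}" for i in range(1212)}
        b = {f"g{i}" for i in range(173)} | {f"x{i}" for i in range(7)}
        _, size = deg_set_exclusion(a, b)
        assert size == 1039

    def test_disjoint_and_subset_cases(self):
        assert deg_set_exclusion({1, 2}, {3, 4})[1] == 2
        assert deg_set_exclusion({1, 2}, {1, 2, 3})[1] == 0
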