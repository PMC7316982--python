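"""Preclinical (mouse-arm) statistics.

Exact 2x2 contingency tests for aneurysm incidence and rupture rates,
Kaplan-Meier symptom-free curves over the 21-day observation window with
the Mantel-Cox log-rank test, two-group and multi-group comparisons with
Bonferroni control, hypergeometric gene-set enrichment, and
differentially-expressed-gene (DEG) set arithmetic.

Rupture-rate denominators are aneurysm-positive animals only; the
symptom-free curves likewise condition on aneurysm-positive animals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, f_oneway, hypergeom, ttest_ind

from gutmwas.diffabund import bh_adjust, wilcoxon_rank_sum


@dataclass
class TestResult:
    statistic: float
    p: float
    method: str
    df: float | None = None


@dataclass
class SurvivalCurve:
    times: np.ndarray  # ascending event days
    at_risk: np.ndarray  # risk-set size just before each event time
    survival: np.ndarray  # product-limit estimate after each event time
    censored: np.ndarray  # censoring days


def fisher_exact_2x2(table, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table (rows = arms, cols = outcome).

    The two-sided p follows the point-probability rule (the R
    ``fisher.test`` convention): sum the probabilities of all tables with
    the observed margins whose point probability does not exceed the
    observed table's.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative integers")
    a = t[0, 0]
    r1, r2 = t[0].sum(), t[1].sum()
    c1 = t[:, 0].sum()
    n = t.sum()
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return TestResult(statistic=1.0, p=1.0, method="fisher_exact")

    lo, hi = max(0, c1 - r2), min(c1, r1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    assert abs(pmf.sum() - 1.0) < 1e-9  # point probabilities over all tables
    p_obs = hypergeom.pmf(a, n, c1, r1)
    if alternative == "two-sided":
        p = pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()
    elif alternative == "greater":
        p = pmf[support >= a].sum()
    elif alternative == "less":
        p = pmf[support <= a].sum()
    else:
        raise ValueError("alternative must be two-sided, greater, or less")
    odds = (
        (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
        if t[0, 1] * t[1, 0] > 0
        else np.inf
    )
    return TestResult(statistic=float(odds), p=float(min(p, 1.0)), method="fisher_exact")


def _arm_events(outcomes: pd.DataFrame, arm: str) -> tuple[np.ndarray, np.ndarray]:
    sub = outcomes[(outcomes["arm"] == arm) & outcomes["aneurysm"]]
    if len(sub) == 0:
        raise ValueError(f"arm {arm!r} has no aneurysm-positive animals")
    return sub["onset_day"].values.astype(float), (~sub["censored"]).values


def km_curve(outcomes: pd.DataFrame, arm: str) -> SurvivalCurve:
    """Product-limit symptom-free curve for one arm.

    Restricted to aneurysm-positive animals; symptomatic animals are events
    at their onset day, all others are censored at day 21.
    ``S(t) = prod_{t_i <= t} (1 - d_i / n_i)``.
    """
    days, event = _arm_events(outcomes, arm)
    order = np.argsort(days, kind="mergesort")
    days, event = days[order], event[order]
    event_times = np.unique(days[event])
    n_at_risk = []
    surv = []
    s = 1.0
    for t in event_times:
        n_i = (days >= t).sum()
        d_i = ((days == t) & event).sum()
        s *= 1.0 - d_i / n_i
        n_at_risk.append(n_i)
        surv.append(s)
    return SurvivalCurve(
        times=event_times,
        at_risk=np.array(n_at_risk),
        survival=np.array(surv),
        censored=days[~event],
    )


def logrank_test(outcomes: pd.DataFrame, arms: list[str] | None = None) -> TestResult:
    """Mantel-Cox log-rank test across arms (aneurysm-positive animals).

    At each event time the observed events per arm are compared with their
    hypergeometric expectation given the pooled risk set; the quadratic form
    of the summed differences against the summed covariance is chi-square
    with (number of arms - 1) degrees of freedom.
    """
    if arms is None:
        arms = sorted(outcomes["arm"].unique())
    if len(arms) < 2:
        raise ValueError("need at least 2 arms")
    per_arm = [_arm_events(outcomes, a) for a in arms]
    k = len(arms)

    all_days = np.concatenate([d for d, _ in per_arm])
    all_event = np.concatenate([e for _, e in per_arm])
    arm_of = np.concatenate([np.full(len(d), g) for g, (d, _) in enumerate(per_arm)])
    if not all_event.any():
        warnings.warn("no events in any arm; log-rank p = 1", stacklevel=2)
        return TestResult(statistic=0.0, p=1.0, method="logrank", df=float(k - 1))

    times = np.unique(all_days[all_event])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in times:
        at_risk = all_days >= t
        n = at_risk.sum()
        d = (at_risk & all_event & (all_days == t)).sum()
        n_g = np.array([(at_risk & (arm_of == g)).sum() for g in range(k)])
        d_g = np.array(
            [(at_risk & all_event & (all_days == t) & (arm_of == g)).sum() for g in range(k)]
        )
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            V += (
                d
                * (n - d)
                / (n - 1)
                * (np.diag(frac) - np.outer(frac, frac))
            )
    z = (O - E)[: k - 1]
    Vsub = V[: k - 1, : k - 1]
    try:
        stat = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(Vsub) @ z)
    p = float(chi2.sf(stat, df=k - 1))
    return TestResult(statistic=stat, p=p, method="logrank", df=float(k - 1))


def group_compare(values, groups, method: str = "t_test"):
    """Two- or multi-group comparison.

    ``t_test``: Student's unpaired two-tailed t-test.
    ``mann_whitney_exact``: exact two-sided Wilcoxon rank-sum test.
    ``anova_bonferroni``: one-way ANOVA followed by Bonferroni-corrected
    pairwise t-tests; returns (anova TestResult, {pair: TestResult}).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = list(pd.unique(groups))
    parts = [values[groups == g] for g in uniq]

    if method == "t_test":
        if len(uniq) != 2:
            raise ValueError("t_test requires exactly 2 groups")
        if all(p.std(ddof=1) == 0 for p in parts):
            raise ValueError("zero within-group variance")
        stat, p = ttest_ind(parts[0], parts[1])
        return TestResult(float(stat), float(p), "t_test", df=float(len(values) - 2))

    if method == "mann_whitney_exact":
        if len(uniq) != 2:
            raise ValueError("mann_whitney_exact requires exactly 2 groups")
        U, p = wilcoxon_rank_sum(parts[0], parts[1], mode="exact")
        return TestResult(float(U), float(p), "mann_whitney_exact")

    if method == "anova_bonferroni":
        if len(uniq) < 3:
            raise ValueError("anova_bonferroni is for more than 2 groups")
        if all(p.std(ddof=1) == 0 for p in parts):
            raise ValueError("zero within-group variance")
        F, p = f_oneway(*parts)
        anova = TestResult(float(F), float(p), "anova", df=float(len(uniq) - 1))
        n_pairs = len(uniq) * (len(uniq) - 1) // 2
        pairwise = {}
        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                t, pp = ttest_ind(parts[i], parts[j])
                pairwise[(uniq[i], uniq[j])] = TestResult(
                    float(t), float(min(pp * n_pairs, 1.0)), "t_test_bonferroni"
                )
        return anova, pairwise

    raise ValueError(f"unknown method {method!r}")


@dataclass
class EnrichmentResult:
    term_id: str
    overlap: int
    term_size: int
    de_size: int
    universe_size: int
    p: float
    q: float = np.nan


def hypergeom_enrichment(
    de_set, term_map: dict, universe, alpha_q: float = 0.05
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a DEG set against terms.

    ``p = P[X >= overlap]`` for X hypergeometric(universe, term, de); BH
    across terms. Returns all terms with a ``significant`` flag at
    q < ``alpha_q``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    de = set(de_set) & universe
    rows = []
    for term, members in term_map.items():
        members = set(members) & universe
        k = len(de & members)
        p = float(hypergeom.sf(k - 1, len(universe), len(members), len(de)))
        rows.append(
            {
                "term_id": term,
                "overlap": k,
                "term_size": len(members),
                "de_size": len(de),
                "universe_size": len(universe),
                "p": min(p, 1.0),
            }
        )
    res = pd.DataFrame(rows)
    res["q"] = bh_adjust(res["p"].values)
    res["significant"] = res["q"] < alpha_q
    return res.sort_values(["q", "term_id"], kind="mergesort").reset_index(drop=True)


def deg_set_exclusion(set_a, set_b) -> tuple[set, int]:
    """Genes specific to A: ``A \\ (A intersect B)`` and its size."""
    a, b = set(set_a), set(set_b)
    specific = a - b
    return specific, len(specific)
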