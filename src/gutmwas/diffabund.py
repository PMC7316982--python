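"""Two-group differential abundance: Wilcoxon rank-sum + Benjamini-Hochberg.

The per-feature test is the two-sided Wilcoxon (Mann-Whitney) rank-sum test
with midranks for ties; the normal approximation uses the tie-corrected
variance and, by design, no continuity correction (the large-sample
``wilcox.test(correct=FALSE)`` path common in metagenomics pipelines).
Exact enumeration is available for tie-free data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata


def wilcoxon_rank_sum(x, y, mode: str = "normal_approx") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of the first
    sample. ``mode='exact'`` enumerates all C(n1+n2, n1) group assignments
    (valid only without ties; with ties it falls back to the normal
    approximation with a warning). ``mode='normal_approx'`` applies the
    tie-corrected normal approximation without continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    R1 = ranks[:n1].sum()
    U = R1 - n1 * (n1 + 1) / 2.0

    has_ties = np.unique(pooled).size < pooled.size
    if mode == "exact":
        if has_ties:
            warnings.warn(
                "ties present: exact enumeration invalid, using normal approximation",
                stacklevel=2,
            )
            mode = "normal_approx"
        else:
            return _exact_wilcoxon(pooled, n1, U)
    if mode != "normal_approx":
        raise ValueError("mode must be 'exact' or 'normal_approx'")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(U), 1.0  # all values tied
    z = (U - mu) / np.sqrt(var)
    from scipy.stats import norm

    p = 2.0 * norm.sf(abs(z))
    return float(U), float(min(p, 1.0))


def _exact_wilcoxon(pooled: np.ndarray, n1: int, U_obs: float) -> tuple[float, float]:
    """Enumerate every assignment of n1 pooled values to the first group."""
    n = pooled.size
    ranks = rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    dev_obs = abs(U_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), n1):
        R1 = ranks[list(idx)].sum()
        U = R1 - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(U - mu) >= dev_obs - 1e-12:
            count += 1
    return float(U_obs), count / total


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class DifferentialFeature:
    feature_id: str
    statistic: float
    p: float
    q: float
    direction: str  # case_enriched / control_enriched
    mean_case: float
    mean_control: float


def differential_features(
    table,
    alpha_q: float = 0.05,
    mode: str = "normal_approx",
    direction_by: str = "mean",
    min_prevalence: float = 0.0,
) -> pd.DataFrame:
    """Per-feature Wilcoxon + BH across features; features with q < alpha_q.

    Direction comes from the comparison of group arithmetic means of relative
    abundance (``direction_by='median'`` uses medians). Features observed in
    fewer than ``min_prevalence`` of samples are dropped before testing
    (default 0: no prevalence filter). Output rows are ordered by q then
    feature id and restricted to q < alpha_q.
    """
    case = table.group_columns("case")
    control = table.group_columns("control")
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")

    data = table.data
    if min_prevalence > 0:
        prev = (data > 0).mean(axis=1)
        data = data.loc[prev >= min_prevalence]
        case, control = case.loc[data.index], control.loc[data.index]

    stat_fn = np.median if direction_by == "median" else np.mean
    rows = []
    for fid in data.index:
        x, y = case.loc[fid].values, control.loc[fid].values
        U, p = wilcoxon_rank_sum(x, y, mode=mode)
        rows.append(
            {
                "feature_id": fid,
                "statistic": U,
                "p": p,
                "mean_case": float(np.mean(x)),
                "mean_control": float(np.mean(y)),
                "direction": (
                    "case_enriched" if stat_fn(x) >= stat_fn(y) else "control_enriched"
                ),
            }
        )
    res = pd.DataFrame(rows)
    res["q"] = bh_adjust(res["p"].values)
    res = res[res["q"] < alpha_q]
    res = res.sort_values(["q", "feature_id"], kind="mergesort").reset_index(drop=True)
    return res[
        ["feature_id", "statistic", "p", "q", "direction", "mean_case", "mean_control"]
    ]
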