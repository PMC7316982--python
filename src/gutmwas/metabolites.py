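"""Species-metabolite Spearman association with BH control and clustering.

All species-metabolite pairs are tested with Spearman's rank correlation;
the p-value grid is BH-adjusted; cells with |rho| < 0.4 are masked from
display; rows and columns are ordered by hierarchical clustering on the
correlation distance (1 - Pearson of rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, single, complete, ward, leaves_list
from scipy.spatial.distance import squareform
from scipy.stats import rankdata, t as t_dist

from gutmwas.containers import MetabolitePanel, as_frame
from gutmwas.diffabund import bh_adjust

_LINKAGES = {"average": average, "single": single, "complete": complete, "ward": ward}


def spearman(x, y, exact_n_max: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with an exact small-sample p-value.

    rho is the Pearson correlation of midranks. For n <= ``exact_n_max`` the
    two-sided p comes from the full permutation distribution of rho;
    otherwise from the t-approximation with n - 2 degrees of freedom.
    Zero-variance input raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    rx, ry = rankdata(x), rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero-variance input: Spearman undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_n_max:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
        count = 0
        total = 0
        for perm in permutations(range(n)):
            r = float(rxc @ ryc[list(perm)]) / denom
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return rho, count / total

    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * t_dist.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def hierarchical_cluster(
    matrix, linkage: str = "average"
) -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of rows on the correlation distance.

    ``d = 1 - Pearson(row_a, row_b)``; a constant row has undefined
    correlation and its distances are set to 1 with a warning. Returns
    ``(leaf_order, merge_tree)`` where merge_tree is the scipy linkage
    matrix (deterministic: ties resolve to lower indices via scipy's
    ordering).
    """
    M = matrix.values if isinstance(matrix, pd.DataFrame) else np.asarray(matrix)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 rows to cluster")
    const = M.std(axis=1) == 0
    if const.any():
        warnings.warn("constant rows: correlation undefined, distance set to 1", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(M)
    D = 1.0 - C
    D[np.isnan(D)] = 1.0
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    Z = _LINKAGES[linkage](squareform(D, checks=False))
    return leaves_list(Z), Z


@dataclass
class CorrelationHeatmap:
    rho: pd.DataFrame  # species x metabolites
    p: pd.DataFrame
    q: pd.DataFrame
    mask: pd.DataFrame  # True = shown (|rho| >= r_mask)
    marks: pd.DataFrame  # '' / '+' (p < 0.05) / '*' (p < 0.01)
    row_order: np.ndarray
    col_order: np.ndarray

    def to_long(self) -> pd.DataFrame:
        """Ordered long-format table for plotting."""
        rows = []
        for i in self.row_order:
            for j in self.col_order:
                rows.append(
                    {
                        "species": self.rho.index[i],
                        "metabolite": self.rho.columns[j],
                        "rho": self.rho.iat[i, j],
                        "p": self.p.iat[i, j],
                        "q": self.q.iat[i, j],
                        "shown": bool(self.mask.iat[i, j]),
                        "mark": self.marks.iat[i, j],
                    }
                )
        return pd.DataFrame(rows)


def correlation_heatmap(
    species,
    metabolites,
    r_mask: float = 0.4,
    mark_levels: tuple[float, float] = (0.05, 0.01),
    mark_on: str = "q",
    linkage: str = "average",
) -> CorrelationHeatmap:
    """All pairwise species-metabolite Spearman correlations, masked and marked.

    BH runs across the full grid. Cells with |rho| < ``r_mask`` are hidden
    (strict: |rho| == r_mask stays shown). Significance marks use the
    BH-adjusted values by default (``mark_on='p'`` switches to raw p).
    """
    sp = as_frame(species)
    met = (
        metabolites.concentrations
        if isinstance(metabolites, MetabolitePanel)
        else as_frame(metabolites)
    )
    shared = sp.columns.intersection(met.columns)
    if len(shared) == 0:
        raise ValueError("species and metabolites share no samples")
    sp, met = sp[shared], met[shared]

    ns, nm = sp.shape[0], met.shape[0]
    rho = np.empty((ns, nm))
    p = np.empty((ns, nm))
    for i in range(ns):
        for j in range(nm):
            rho[i, j], p[i, j] = spearman(sp.values[i], met.values[j])
    q = bh_adjust(p.ravel()).reshape(ns, nm)

    sig = q if mark_on == "q" else p
    loose, tight = mark_levels
    marks = np.where(sig < tight, "*", np.where(sig < loose, "+", ""))
    shown = np.abs(rho) >= r_mask

    row_order, _ = hierarchical_cluster(rho, linkage=linkage)
    col_order, _ = hierarchical_cluster(rho.T, linkage=linkage)

    idx, cols = sp.index, met.index
    return CorrelationHeatmap(
        rho=pd.DataFrame(rho, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        q=pd.DataFrame(q, index=idx, columns=cols),
        mask=pd.DataFrame(shown, index=idx, columns=cols),
        marks=pd.DataFrame(marks, index=idx, columns=cols),
        row_order=row_order,
        col_order=col_order,
    )
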