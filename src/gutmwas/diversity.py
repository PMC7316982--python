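"""Rarefaction, alpha/beta diversity, PCoA ordination, and ANOSIM.

Shannon index defaults to base 2 (the QIIME v1 convention); Bray-Curtis is
the beta-diversity metric; PCoA is classical metric scaling via Gower
double-centering; ANOSIM is the rank-based permutation test of
between-group vs within-group dissimilarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from gutmwas.containers import as_frame


@dataclass
class OrdinationResult:
    """PCoA embedding: sample coordinates plus the eigenvalue spectrum."""

    coordinates: pd.DataFrame  # sample-by-axis, positive-eigenvalue axes only
    eigenvalues: np.ndarray  # full spectrum, descending (negatives reported)
    proportion_explained: np.ndarray  # per retained axis


@dataclass
class AnosimResult:
    R: float
    p: float
    n_permutations: int


def rarefaction_curve(
    counts,
    subsample_sizes,
    n_repeats: int = 100,
    seed: int = 0,
):
    """Mean gene richness at each subsampling depth.

    Parameters
    ----------
    counts:
        1-D nonnegative integer vector of per-gene counts (a pooled sample),
        or a gene-by-sample DataFrame — then each column is rarefied
        separately.
    subsample_sizes:
        Depths to subsample at, each <= the total count of the pool.
    n_repeats:
        Random subsamples (without replacement) averaged per depth.

    Returns a Series (depth -> mean richness) for a vector input, or a
    DataFrame (depth x sample) for a table input.
    """
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(
            {
                col: rarefaction_curve(counts[col].values, subsample_sizes, n_repeats, seed)
                for col in counts.columns
            }
        )
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    counts = counts.astype(np.int64)
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    out = {}
    for m in subsample_sizes:
        m = int(m)
        if m > total:
            raise ValueError(f"subsample size {m} exceeds pool of {total}")
        if m == 0:
            out[m] = 0.0
            continue
        rich = np.empty(n_repeats)
        for r in range(n_repeats):
            draw = rng.multivariate_hypergeometric(counts, m)
            rich[r] = np.count_nonzero(draw)
        out[m] = float(rich.mean())
    return pd.Series(out, name="mean_richness")


def expected_richness(counts, m: int) -> float:
    """Closed-form mean richness of a without-replacement subsample of size m.

    ``E[S] = sum_i (1 - C(N - N_i, m) / C(N, m))`` — the hypergeometric
    probability that gene i appears at least once.
    """
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=np.int64)
    N = counts.sum()

    def logC(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    p_absent = np.where(
        N - counts >= m, np.exp(logC(N - counts, m) - logC(N, m)), 0.0
    )
    return float((1.0 - p_absent).sum())


def shannon_index(abundance, base: float = 2.0) -> float:
    """Shannon diversity ``H = -sum p_i log_base p_i`` after renormalization."""
    p = np.asarray(abundance, dtype=float)
    if (p < 0).any():
        raise ValueError("abundances must be nonnegative")
    s = p.sum()
    if s <= 0:
        raise ValueError("all-zero abundance vector")
    p = p[p > 0] / s
    return float(-(p * np.log(p)).sum() / np.log(base))


def bray_curtis(table) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between samples.

    ``d(x, y) = sum |x_i - y_i| / sum (x_i + y_i)``. Accepts an
    AbundanceTable or a feature-by-sample DataFrame; a pair of all-zero
    samples is undefined and raises.
    """
    data = as_frame(table)
    X = data.values.T  # samples in rows for pdist
    if (X < 0).any():
        raise ValueError("abundances must be nonnegative")
    zero = X.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValueError("Bray-Curtis undefined for a pair of all-zero samples")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=data.columns, columns=data.columns)


def pcoa(distance_matrix) -> OrdinationResult:
    """Principal coordinate analysis of a symmetric zero-diagonal distance matrix.

    Gower-centers ``-d^2 / 2``, eigendecomposes, and scales eigenvectors by
    the square root of their (positive) eigenvalues. Negative eigenvalues are
    reported in the spectrum but contribute no axes (no Cailliez/Lingoes
    correction).
    """
    D = distance_matrix
    labels = D.index if isinstance(D, pd.DataFrame) else None
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    evals, evecs = np.linalg.eigh((G + G.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals).max(initial=1.0))
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total = evals[evals > 0].sum()
    prop = evals[pos] / total if total > 0 else np.zeros(pos.sum())
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    index = labels if labels is not None else pd.RangeIndex(n)
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=index, columns=axes),
        eigenvalues=evals,
        proportion_explained=prop,
    )


def _anosim_r(rank_matrix: np.ndarray, labels: np.ndarray) -> float:
    n = rank_matrix.shape[0]
    within = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    ranks = rank_matrix[iu]
    w = within[iu]
    M = n * (n - 1) / 2
    return float((ranks[~w].mean() - ranks[w].mean()) / (M / 2.0))


def anosim(
    distance_matrix,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities: rank-based group-separation permutation test.

    All pairwise distances are ranked jointly; ``R = (mean between-group
    rank - mean within-group rank) / (M / 2)`` with ``M = n(n-1)/2``. The
    permutation p-value carries the add-one correction
    ``p = (#{R_perm >= R_obs} + 1) / (n_permutations + 1)`` so it is never 0.
    """
    D = np.asarray(distance_matrix, dtype=float)
    if isinstance(groups, pd.Series):
        if isinstance(distance_matrix, pd.DataFrame):
            groups = groups.loc[distance_matrix.index]
        groups = groups.values
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("ANOSIM requires at least 2 groups")
    if (counts < 2).any():
        raise ValueError("every group must contain at least 2 samples")

    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    rank_flat = rankdata(D[iu])
    R_mat = np.zeros((n, n))
    R_mat[iu] = rank_flat
    R_mat = R_mat + R_mat.T

    r_obs = _anosim_r(R_mat, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if _anosim_r(R_mat, perm) >= r_obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return AnosimResult(R=r_obs, p=p, n_permutations=n_permutations)
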