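"""SparCC: basis correlations from compositional abundance data.

Relative abundances only constrain ratios, so naive Pearson correlations of
fractions carry closure artifacts. SparCC estimates the correlations of the
unobserved *basis* abundances from the log-ratio variances
``t_ij = Var(log(x_i / x_j))``: under a sparsity assumption the basis
variances ``w`` solve a linear system in the row sums of ``t``, and

    rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).

Strongly correlated pairs violate the sparsity assumption, so the strongest
pair above an exclusion threshold is iteratively removed from the system
and the solve repeated. Sampling noise is integrated out by resampling the
fractions from a per-sample Dirichlet posterior and taking the median
estimate over draws.

Edges of the co-occurrence network are pairs with |basis correlation|
beyond +/-0.5 and a BH-adjusted permutation pseudo-p below 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from gutmwas.containers import as_frame
from gutmwas.diffabund import bh_adjust


@dataclass
class SparccConfig:
    """Defaults follow the original SparCC release."""

    n_exclusion_iterations: int = 20
    exclusion_threshold: float = 0.1
    n_dirichlet_draws: int = 20
    n_permutations: int = 100
    pseudo_depth: float = 10_000.0  # fractions -> pseudo-counts for the Dirichlet
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.exclusion_threshold < 1.0:
            raise ValueError("exclusion_threshold must lie in (0, 1)")
        for name in ("n_exclusion_iterations", "n_dirichlet_draws", "n_permutations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def _log_ratio_variances(fracs: np.ndarray) -> np.ndarray:
    """t_ij = Var(log x_i - log x_j), from the covariance of log fractions."""
    L = np.log(fracs)
    cov = np.cov(L)
    v = np.diag(cov)
    return v[:, None] + v[None, :] - 2.0 * cov


def _basis_correlations(
    T: np.ndarray, n_iter: int, threshold: float
) -> np.ndarray:
    """Solve for basis variances and correlations with pair exclusion."""
    D = T.shape[0]
    # M w = t_rowsum with M = (D-2) I + 1; exclusions decrement the system.
    # Excluded pairs drop out of the variance solve but their correlation is
    # still computed from the original log-ratio variance.
    M = np.ones((D, D)) + (D - 2) * np.eye(D)
    t_sys = T.copy()
    excluded = np.zeros((D, D), dtype=bool)

    def solve() -> tuple[np.ndarray, np.ndarray]:
        w = np.linalg.solve(M, t_sys.sum(axis=1))
        w = np.clip(w, 1e-12, None)
        rho = (w[:, None] + w[None, :] - T) / (2.0 * np.sqrt(np.outer(w, w)))
        return w, np.clip(rho, -1.0, 1.0)

    w, rho = solve()
    for _ in range(n_iter):
        cand = np.abs(rho)
        cand[np.eye(D, dtype=bool) | excluded] = 0.0
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= threshold:
            break
        excluded[i, j] = excluded[j, i] = True
        for a, b in ((i, j), (j, i)):
            M[a, a] -= 1.0
            M[a, b] -= 1.0
            t_sys[a, b] = 0.0
        # a component excluded against everyone would make M singular
        if (excluded.sum(axis=1) >= D - 2).any():
            break
        w, rho = solve()
    np.fill_diagonal(rho, 1.0)
    return rho


def sparcc_correlation(data, config: SparccConfig | None = None) -> pd.DataFrame:
    """Median-over-Dirichlet-draws SparCC basis correlation matrix.

    ``data`` is feature-by-sample counts or fractions (an AbundanceTable or
    DataFrame/array). Needs >= 4 features; zero-variance features raise.
    """
    config = config or SparccConfig()
    frame = as_frame(data)
    labels = frame.index
    X = np.asarray(frame, dtype=float)
    D, n = X.shape
    if D < 4:
        raise ValueError("SparCC needs at least 4 features")
    if (X.std(axis=1) == 0).any():
        raise ValueError("zero-variance feature")

    # treat fraction input as pseudo-counts so the Dirichlet has mass to vary
    if np.allclose(X.sum(axis=0), 1.0, atol=1e-6):
        X = X * config.pseudo_depth

    rng = np.random.default_rng(config.seed)
    draws = np.empty((config.n_dirichlet_draws, D, D))
    for k in range(config.n_dirichlet_draws):
        fracs = np.empty_like(X)
        for s in range(n):
            fracs[:, s] = rng.dirichlet(X[:, s] + 1.0)
        T = _log_ratio_variances(fracs)
        draws[k] = _basis_correlations(
            T, config.n_exclusion_iterations, config.exclusion_threshold
        )
    rho = np.median(draws, axis=0)
    np.fill_diagonal(rho, 1.0)
    if labels is not None:
        return pd.DataFrame(rho, index=labels, columns=labels)
    return pd.DataFrame(rho)


def pseudo_pvalues(
    data, observed_rho, config: SparccConfig | None = None
) -> pd.DataFrame:
    """Permutation pseudo-p-values for each SparCC correlation.

    Every permutation shuffles each feature's values across samples
    independently (destroying all covariation while keeping margins), then
    recomputes the SparCC matrix. Two-sided extremity with the add-one
    correction: ``p_ij = (#{|rho_perm| >= |rho_obs|} + 1) / (N + 1)``.
    """
    config = config or SparccConfig()
    frame = as_frame(data)
    labels = frame.index
    X = np.asarray(frame, dtype=float)
    obs = np.abs(np.asarray(observed_rho, dtype=float))
    if obs.shape != (X.shape[0], X.shape[0]):
        raise ValueError("observed_rho does not match the data dimensions")

    rng = np.random.default_rng(config.seed + 1)
    exceed = np.zeros_like(obs)
    perm_cfg = SparccConfig(
        n_exclusion_iterations=config.n_exclusion_iterations,
        exclusion_threshold=config.exclusion_threshold,
        n_dirichlet_draws=config.n_dirichlet_draws,
        n_permutations=config.n_permutations,
        pseudo_depth=config.pseudo_depth,
        seed=config.seed,
    )
    for b in range(config.n_permutations):
        Xp = np.array([rng.permutation(row) for row in X])
        perm_cfg.seed = config.seed + 10_000 + b
        rho_p = np.abs(sparcc_correlation(Xp, perm_cfg).values)
        exceed += rho_p >= obs - 1e-12
    p = (exceed + 1.0) / (config.n_permutations + 1.0)
    np.fill_diagonal(p, 1.0)
    if labels is not None:
        return pd.DataFrame(p, index=labels, columns=labels)
    return pd.DataFrame(p)


def build_network(
    rho,
    p,
    pos_min: float = 0.5,
    neg_max: float = -0.5,
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Threshold the correlation/pseudo-p matrices into a signed edge list.

    BH runs over the upper-triangle p-values; an edge survives when
    ``rho > pos_min`` or ``rho < neg_max`` (strict) and ``q < q_max``.
    Returns columns (feature_i, feature_j, rho, pseudo_p, q, sign) with
    i < j in matrix order.
    """
    rho_df = rho if isinstance(rho, pd.DataFrame) else pd.DataFrame(rho)
    p_arr = np.asarray(p, dtype=float)
    R = rho_df.values
    D = R.shape[0]
    iu = np.triu_indices(D, k=1)
    q_flat = bh_adjust(p_arr[iu])
    rows = []
    names = list(rho_df.index)
    for (i, j), q in zip(zip(*iu), q_flat):
        r = R[i, j]
        if (r > pos_min or r < neg_max) and q < q_max:
            rows.append(
                {
                    "feature_i": names[i],
                    "feature_j": names[j],
                    "rho": r,
                    "pseudo_p": p_arr[i, j],
                    "q": q,
                    "sign": "positive" if r > 0 else "negative",
                }
            )
    return pd.DataFrame(
        rows, columns=["feature_i", "feature_j", "rho", "pseudo_p", "q", "sign"]
    )


def edge_list_to_graphml(edges: pd.DataFrame, path) -> None:
    """Write a signed edge list as GraphML for network viewers."""
    import networkx as nx

    G = nx.Graph()
    for _, row in edges.iterrows():
        G.add_edge(
            row["feature_i"],
            row["feature_j"],
            rho=float(row["rho"]),
            q=float(row["q"]),
            sign=row["sign"],
        )
    nx.write_graphml(G, path)


class SparCC(BaseEstimator):
    """Estimator wrapper: fit a SparCC basis-correlation network.

    Parameters mirror :class:`SparccConfig`. After ``fit(X)`` (X is
    sample-by-feature, sklearn orientation) the instance carries
    ``correlation_``, ``pvalues_`` (if ``compute_pvalues``) and ``edges_``.
    """

    def __init__(
        self,
        n_exclusion_iterations: int = 20,
        exclusion_threshold: float = 0.1,
        n_dirichlet_draws: int = 20,
        n_permutations: int = 100,
        compute_pvalues: bool = False,
        pos_min: float = 0.5,
        neg_max: float = -0.5,
        q_max: float = 0.01,
        random_state: int = 0,
    ) -> None:
        self.n_exclusion_iterations = n_exclusion_iterations
        self.exclusion_threshold = exclusion_threshold
        self.n_dirichlet_draws = n_dirichlet_draws
        self.n_permutations = n_permutations
        self.compute_pvalues = compute_pvalues
        self.pos_min = pos_min
        self.neg_max = neg_max
        self.q_max = q_max
        self.random_state = random_state

    def _config(self) -> SparccConfig:
        return SparccConfig(
            n_exclusion_iterations=self.n_exclusion_iterations,
            exclusion_threshold=self.exclusion_threshold,
            n_dirichlet_draws=self.n_dirichlet_draws,
            n_permutations=self.n_permutations,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        features_by_samples = frame.T  # internal orientation
        cfg = self._config()
        self.correlation_ = sparcc_correlation(features_by_samples, cfg)
        if self.compute_pvalues:
            self.pvalues_ = pseudo_pvalues(
                features_by_samples, self.correlation_.values, cfg
            )
            self.edges_ = build_network(
                self.correlation_,
                self.pvalues_.values,
                self.pos_min,
                self.neg_max,
                self.q_max,
            )
        return self
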