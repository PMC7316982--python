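"""Monte-Carlo PLS-DA stability feature selection.

A PLS-DA model is fit on N random half-size resamples of the cohort; for
each variable j the resampled regression coefficients ``beta_ij`` yield a
stability statistic

    c_j = mean_i(beta_ij) / sd_i(beta_ij),       sd with denominator N - 1.

Variables whose coefficient keeps both a large magnitude and a stable sign
across resamples attain large |c_j|. The selected set is chosen by scanning
|c_j| cutoffs and keeping the cutoff that maximizes k-fold cross-validated
PLS-DA accuracy (ties resolve to the larger cutoff, i.e. fewer variables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_X_y, check_array


class PLSDAClassifier(BaseEstimator, ClassifierMixin):
    """PLS discriminant analysis via NIPALS on a dummy-coded response.

    X is column-centered and, by default, autoscaled to unit variance (the
    chemometrics convention; it makes downstream coefficient-stability
    statistics exactly invariant to positive column rescaling); y is coded
    0/1 and centered. NIPALS extracts ``n_components`` orthogonal score
    vectors; the composite regression coefficient vector
    ``beta = W (P'W)^-1 q`` is reported on the original (unscaled) axis so
    predictions are ``(X - mean) @ beta``. Prediction thresholds the
    continuous score at the centered midpoint.
    """

    def __init__(
        self,
        n_components: int = 2,
        scale: bool = True,
        max_iter: int = 500,
        tol: float = 1e-9,
    ):
        self.n_components = n_components
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X, y = check_X_y(X, np.asarray(y))
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) != 2:
            raise ValueError("PLS-DA requires exactly two classes")
        yc = y_idx.astype(float)

        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = yc.mean()
        Xc = X - self.x_mean_
        u = yc - self.y_mean_

        sd = Xc.std(axis=0, ddof=1)
        zero_var = sd == 0
        if zero_var.any():
            warnings.warn("zero-variance columns receive coefficient 0", stacklevel=2)
        if self.scale:
            self.x_std_ = np.where(zero_var, 1.0, sd)
            Xc = Xc / self.x_std_
        else:
            self.x_std_ = np.ones_like(sd)

        n, p = Xc.shape
        k = min(self.n_components, p, n - 1)
        W = np.zeros((p, k))
        P = np.zeros((p, k))
        q = np.zeros(k)
        T = np.zeros((n, k))
        Xd = Xc.copy()
        for a in range(k):
            # single-response NIPALS: weights converge in one step
            w = Xd.T @ u
            norm = np.linalg.norm(w)
            if norm < self.tol:
                k = a
                break
            w /= norm
            t = Xd @ w
            tt = t @ t
            if tt < self.tol:
                k = a
                break
            pvec = Xd.T @ t / tt
            q[a] = u @ t / tt
            Xd = Xd - np.outer(t, pvec)
            W[:, a], P[:, a], T[:, a] = w, pvec, t
        W, P, q, T = W[:, :k], P[:, :k], q[:k], T[:, :k]

        if k == 0:
            self.coef_ = np.zeros(p)
        else:
            self.coef_ = (W @ np.linalg.solve(P.T @ W, q)) / self.x_std_
        self.coef_[zero_var] = 0.0
        self.x_weights_ = W
        self.x_loadings_ = P
        self.x_scores_ = T
        self.n_components_ = k
        return self

    def decision_function(self, X):
        X = check_array(X)
        return (X - self.x_mean_) @ self.coef_

    def predict(self, X):
        # centered midpoint: score > 0 -> class coded 1
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def score_continuous(self, X):
        """Uncentered continuous score (for ROC analysis)."""
        return self.decision_function(X) + self.y_mean_


@dataclass
class McConfig:
    """Monte-Carlo resampling configuration.

    ``M`` defaults to half the samples; ``N`` defaults to ``min(n^2, cap)``
    (the full n^2 schedule is configurable but quadratic in cohort size).
    """

    n_components: int = 2
    M: int | None = None
    N: int | None = None
    cap: int = 2000
    cutoff_grid: tuple = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0)
    k_folds: int = 4
    seed: int = 0
    max_redraws: int = 100

    def resolve(self, n: int) -> tuple[int, int]:
        M = self.M if self.M is not None else n // 2
        if not 1 <= M < n:
            raise ValueError("resample size M must satisfy 1 <= M < n")
        N = self.N if self.N is not None else min(n * n, self.cap)
        if N < 2:
            raise ValueError("need at least 2 resamples")
        if not self.cutoff_grid or list(self.cutoff_grid) != sorted(self.cutoff_grid):
            raise ValueError("cutoff_grid must be nonempty and ascending")
        return M, N


@dataclass
class StabilityResult:
    beta_resamples: np.ndarray  # N x p
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    c: np.ndarray  # NaN where sd == 0
    feature_ids: list
    selected: list = field(default_factory=list)
    accuracy_by_cutoff: list = field(default_factory=list)  # (cutoff, accuracy)
    importance: dict = field(default_factory=dict)


def _stratified_resample(
    rng: np.random.Generator, y01: np.ndarray, M: int
) -> np.ndarray:
    """Draw M indices without replacement, proportionally from each class."""
    idx0 = np.flatnonzero(y01 == 0)
    idx1 = np.flatnonzero(y01 == 1)
    m1 = int(round(M * len(idx1) / len(y01)))
    m1 = min(max(m1, 1), M - 1, len(idx1))
    m0 = min(M - m1, len(idx0))
    take = np.concatenate(
        [rng.choice(idx0, size=m0, replace=False), rng.choice(idx1, size=m1, replace=False)]
    )
    return np.sort(take)


def mc_stability(X, y, config: McConfig | None = None) -> StabilityResult:
    """Resample, refit PLS-DA, and compute the per-variable c_j statistics."""
    config = config or McConfig()
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        X = X.values
    else:
        X = np.asarray(X, dtype=float)
        feature_ids = list(range(X.shape[1]))
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    y01 = (y == classes[1]).astype(int)

    n, p = X.shape
    M, N = config.resolve(n)
    rng = np.random.default_rng(config.seed)
    betas = np.empty((N, p))
    for i in range(N):
        for attempt in range(config.max_redraws):
            idx = _stratified_resample(rng, y01, M)
            if len(np.unique(y01[idx])) == 2:
                break
        else:
            raise RuntimeError("could not draw a two-class resample")
        model = PLSDAClassifier(n_components=config.n_components)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[idx], y01[idx])
        betas[i] = model.coef_

    beta_mean = betas.mean(axis=0)
    beta_sd = betas.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(beta_sd > 0, beta_mean / beta_sd, np.nan)
    return StabilityResult(
        beta_resamples=betas,
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        c=c,
        feature_ids=feature_ids,
    )


def _cv_accuracy(X, y01, n_components, k_folds, rng) -> float:
    skf = StratifiedKFold(
        n_splits=k_folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    accs = []
    for tr, te in skf.split(X, y01):
        model = PLSDAClassifier(n_components=n_components)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[tr], y01[tr])
        accs.append((model.predict(X[te]) == y01[te]).mean())
    return float(np.mean(accs))


def cutoff_scan(
    stability: StabilityResult, X, y, config: McConfig | None = None
) -> StabilityResult:
    """Scan |c_j| cutoffs, select the one maximizing CV accuracy.

    Cutoffs leaving no variables are skipped; undefined c_j (zero resample
    SD) are excluded from selection. Ties in accuracy resolve to the larger
    cutoff. Fills ``selected``, ``accuracy_by_cutoff``, ``importance`` on the
    result and returns it.
    """
    config = config or McConfig()
    if isinstance(X, pd.DataFrame):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    y01 = (y == classes[1]).astype(int)

    abs_c = np.abs(stability.c)
    rng = np.random.default_rng(config.seed + 1)
    curve = []
    best = None
    for cutoff in config.cutoff_grid:
        keep = np.flatnonzero(~np.isnan(abs_c) & (abs_c > cutoff))
        if keep.size == 0:
            continue
        acc = _cv_accuracy(X[:, keep], y01, config.n_components, config.k_folds, rng)
        curve.append((float(cutoff), acc))
        if best is None or acc >= best[1]:  # >= : ties go to the larger cutoff
            best = (float(cutoff), acc, keep)
    if best is None:
        raise ValueError("every cutoff in the grid empties the variable set")

    _, _, keep = best
    stability.selected = [stability.feature_ids[k] for k in keep]
    stability.accuracy_by_cutoff = curve
    stability.importance = {
        stability.feature_ids[k]: float(abs_c[k]) for k in keep
    }
    return stability


class MonteCarloStabilitySelector(BaseEstimator):
    """sklearn-style transformer: fit selects stable variables, transform filters.

    Fitted attributes: ``c_``, ``beta_mean_``, ``beta_sd_``, ``support_``
    (boolean mask), ``selected_`` (ids), ``accuracy_by_cutoff_``.
    """

    def __init__(
        self,
        n_components: int = 2,
        M: int | None = None,
        N: int | None = None,
        cap: int = 2000,
        cutoff_grid: tuple = McConfig.cutoff_grid,
        k_folds: int = 4,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.M = M
        self.N = N
        self.cap = cap
        self.cutoff_grid = cutoff_grid
        self.k_folds = k_folds
        self.random_state = random_state

    def _config(self) -> McConfig:
        return McConfig(
            n_components=self.n_components,
            M=self.M,
            N=self.N,
            cap=self.cap,
            cutoff_grid=tuple(self.cutoff_grid),
            k_folds=self.k_folds,
            seed=self.random_state,
        )

    def fit(self, X, y):
        cfg = self._config()
        res = cutoff_scan(mc_stability(X, y, cfg), X, y, cfg)
        self.result_ = res
        self.c_ = res.c
        self.beta_mean_ = res.beta_mean
        self.beta_sd_ = res.beta_sd
        self.selected_ = res.selected
        self.accuracy_by_cutoff_ = res.accuracy_by_cutoff
        sel = set(res.selected)
        self.support_ = np.array([f in sel for f in res.feature_ids])
        return self

    def transform(self, X):
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.support_]
        return np.asarray(X)[:, self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
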