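"""Cross-validated case/control classification with ROC/AUC and bootstrap CI.

Protocol: 30 random trials of stratified 4-fold cross-validation; out-of-fold
continuous scores are pooled per trial for ROC analysis; the AUC confidence
interval comes from a stratified percentile bootstrap. The classifier is a
pluggable fit/score contract; the default is a random forest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold


@dataclass
class ClassifierEval:
    roc_points: np.ndarray  # (FPR, TPR) rows, starts (0,0), ends (1,1)
    auc: float
    ci: tuple[float, float]
    fold_accuracies: np.ndarray  # trials x folds
    mean_accuracy: float
    scores: np.ndarray  # out-of-fold scores, trial-averaged
    labels: np.ndarray


def _default_model(seed: int):
    return RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)


def cross_validated_scores(
    X,
    labels,
    model_factory=None,
    n_folds: int = 4,
    n_trials: int = 30,
    seed: int = 0,
):
    """Out-of-fold scores and per-fold accuracies over repeated stratified CV.

    ``X`` is sample-by-feature (an AbundanceTable is transposed
    automatically). ``model_factory(seed)`` must return an object with
    ``fit(X, y)`` and either ``predict_proba`` or ``decision_function``.

    Returns ``(scores, fold_accuracies)``: scores are per-sample out-of-fold
    scores averaged over trials (n_samples,), accuracies are (trials, folds).
    """
    from gutmwas.containers import AbundanceTable

    if isinstance(X, AbundanceTable):  # features x samples -> transpose
        X = X.data.T
    if isinstance(X, pd.DataFrame):
        X = X.values
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary labels required")
    y01 = (y == classes[1]).astype(int)
    if n_folds > min(np.bincount(y01)):
        raise ValueError("n_folds exceeds the smallest class size")
    if model_factory is None:
        model_factory = _default_model

    rng = np.random.default_rng(seed)
    n = len(y01)
    score_sum = np.zeros(n)
    accs = np.empty((n_trials, n_folds))
    for t in range(n_trials):
        skf = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for f, (tr, te) in enumerate(skf.split(X, y01)):
            model = model_factory(int(rng.integers(2**31)))
            model.fit(X[tr], y01[tr])
            if hasattr(model, "predict_proba"):
                s = model.predict_proba(X[te])[:, 1]
                pred = (s > 0.5).astype(int)
            else:
                s = model.decision_function(X[te])
                pred = (s > 0).astype(int)
            score_sum[te] += s
            accs[t, f] = (pred == y01[te]).mean()
    return score_sum / n_trials, accs


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC curve by threshold sweep and trapezoidal AUC.

    The AUC equals the tie-averaged Mann-Whitney concordance
    ``U / (n1 * n2)``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("both classes must be present")
    pos = y == classes[1]
    n_pos, n_neg = pos.sum(), (~pos).sum()

    order = np.argsort(-s, kind="mergesort")
    s_sorted, pos_sorted = s[order], pos[order]
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(~pos_sorted)
    # collapse tied thresholds: keep the last index of each distinct score
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def auc_bootstrap_ci(
    scores, labels, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile-bootstrap interval for the AUC."""
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    pos_idx = np.flatnonzero(y == classes[1])
    neg_idx = np.flatnonzero(y == classes[0])
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        bi = np.concatenate(
            [
                rng.choice(pos_idx, size=len(pos_idx), replace=True),
                rng.choice(neg_idx, size=len(neg_idx), replace=True),
            ]
        )
        _, aucs[b] = roc_auc(s[bi], y[bi])
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(aucs, alpha)),
        float(np.quantile(aucs, 1.0 - alpha)),
    )


def evaluate_classifier(
    X,
    labels,
    model_factory=None,
    n_folds: int = 4,
    n_trials: int = 30,
    n_boot: int = 1000,
    seed: int = 0,
) -> ClassifierEval:
    """Full evaluation: repeated CV, ROC/AUC, and bootstrap CI."""
    scores, accs = cross_validated_scores(
        X, labels, model_factory, n_folds, n_trials, seed
    )
    y = np.asarray(labels)
    roc, auc = roc_auc(scores, y)
    ci = auc_bootstrap_ci(scores, y, n_boot=n_boot, seed=seed + 1)
    return ClassifierEval(
        roc_points=roc,
        auc=auc,
        ci=ci,
        fold_accuracies=accs,
        mean_accuracy=float(accs.mean()),
        scores=scores,
        labels=y,
    )
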