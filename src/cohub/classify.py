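"""Hub-gene-signature classification with cross-validated ROC analysis.

The hub genes selected for a trait form a compact signature; an
elastic-net logistic model on that signature is evaluated by stratified
k-fold cross-validation (default 10-fold): each sample is scored exactly
once by a model that never saw it.  Discrimination is summarized by the
ROC curve and its AUC, computed as the Mann-Whitney concordance
probability (ties counted 1/2), with significance from a label
permutation test using add-one smoothing:

    p = (1 + #{permuted AUC >= observed AUC}) / (1 + n_perm).

A validation-set mode fits once on the training study and scores an
untouched study with the same machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from cohub.elasticnet import ElasticNetFit, ElasticNetLogistic

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    """ROC curve, AUC and (optionally) its permutation p-value."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int
    p_value: float = float("nan")

    def summary(self) -> str:
        out = (
            f"AUC = {self.auc:.3f}  "
            f"(n_pos={self.n_pos}, n_neg={self.n_neg})"
        )
        if not np.isnan(self.p_value):
            out += f"  permutation p = {self.p_value:.4g}"
        return out


def stratified_kfold(labels: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1) per sample, stratified by class.

    Folds are sized within one of each other with per-fold class
    proportions within one sample of the global proportions; identical
    seeds give identical assignments.
    """
    labels = np.asarray(labels)
    minority = int(min((labels == 1).sum(), (labels == 0).sum()))
    if k > minority:
        raise ValueError(f"k={k} exceeds minority class count {minority}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(labels.size, dtype=int)
    for fold, (_, test) in enumerate(skf.split(np.zeros(labels.size), labels)):
        folds[test] = fold
    return folds


def crossvalidated_scores(
    X: np.ndarray,
    y: np.ndarray,
    folds: np.ndarray,
    alpha: float = 0.5,
    lambda_rule: str = "cv",
    lam: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold predicted probabilities, one per sample.

    For every fold, an elastic-net logistic model is fitted on the
    complement (penalty chosen by internal CV unless ``lambda_rule`` is
    "fixed") and applied to the held-out fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    folds = np.asarray(folds)
    rng = np.random.default_rng(seed)
    scores = np.full(y.size, np.nan)
    for fold in np.unique(folds):
        test = folds == fold
        train = ~test
        n_pos = int(y[train].sum())
        n_neg = int(train.sum() - n_pos)
        if n_pos < 2 or n_neg < 2:
            raise ValueError(f"training complement of fold {fold} is degenerate")
        model = ElasticNetLogistic(X[train], y[train], alpha=alpha)
        if lambda_rule == "fixed":
            if lam is None:
                raise ValueError("lambda_rule='fixed' requires lam")
            fit = model.fit(lam)
        else:
            fit = model.fit_cv(
                n_folds=min(5, n_pos, n_neg),
                seed=int(rng.integers(2**31 - 1)),
            )
        scores[test] = fit.predict_proba(X[test])
    return scores


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """ROC curve and AUC (Mann-Whitney concordance, ties counted 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(roc_auc_score(labels, scores))
    return RocResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc, n_pos=n_pos, n_neg=n_neg
    )


def auc_permutation_pvalue(
    scores: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for the observed AUC (add-one smoothing)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    observed = roc_auc_score(labels, scores)
    rng = np.random.default_rng(seed)
    hits = 0
    shuffled = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(shuffled)
        if roc_auc_score(shuffled, scores) >= observed:
            hits += 1
    return (1 + hits) / (1 + n_perm)


def crossvalidated_roc(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    alpha: float = 0.5,
    lambda_rule: str = "cv",
    lam: float | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> RocResult:
    """Stratified k-fold CV ROC of an elastic-net signature classifier."""
    folds = stratified_kfold(y, k, seed=seed)
    scores = crossvalidated_scores(
        X, y, folds, alpha=alpha, lambda_rule=lambda_rule, lam=lam, seed=seed + 1
    )
    result = roc_auc(scores, y)
    if n_perm:
        result.p_value = auc_permutation_pvalue(scores, y, n_perm=n_perm, seed=seed + 2)
    return result


def validation_roc(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    alpha: float = 0.5,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[RocResult, ElasticNetFit]:
    """Fit once on the training study, score an untouched validation study."""
    model = ElasticNetLogistic(np.asarray(X_train, float), np.asarray(y_train, float), alpha=alpha)
    fit = model.fit_cv(seed=seed)
    scores = fit.predict_proba(np.asarray(X_val, float))
    result = roc_auc(scores, y_val)
    if n_perm:
        result.p_value = auc_permutation_pvalue(scores, y_val, n_perm=n_perm, seed=seed + 1)
    return result, fit
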