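"""Sparse panel selection and per-gene diagnostic screening.

L1-penalized logistic regression over a log-spaced lambda grid with
stratified k-fold cross-validation (lambda_min / lambda_1se rules), per-gene
ROC/AUC by the Mann-Whitney formulation, and the AUC + adjusted-p gate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .io import ExpressionStudy

__all__ = ["RegularizationPath", "RocResult", "lasso_cv", "per_gene_auc",
           "diagnostic_gate", "mann_whitney_auc"]

log = logging.getLogger(__name__)

N_LAMBDA = 100
LAMBDA_MIN_RATIO = 1e-4
PROB_EPS = 1e-12


@dataclass(frozen=True)
class RegularizationPath:
    lambdas: np.ndarray
    coef_matrix: np.ndarray  # (n_lambda, n_features), original scale
    intercepts: np.ndarray
    cv_mean: np.ndarray
    cv_se: np.ndarray
    lambda_min: float
    lambda_1se: float
    panel_min: tuple[str, ...]
    panel_1se: tuple[str, ...]
    feature_ids: tuple[str, ...]
    fallback_unpenalized: bool = False

    def to_frame(self) -> pd.DataFrame:
        nnz = (self.coef_matrix != 0).sum(axis=1)
        return pd.DataFrame(
            {"lambda": self.lambdas, "cv_mean": self.cv_mean,
             "cv_se": self.cv_se, "n_nonzero": nnz}
        )


@dataclass(frozen=True)
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    p_adj: float | None = None


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, PROB_EPS, 1 - PROB_EPS)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _fit_l1(x: np.ndarray, y: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """liblinear L1 logistic at penalty lam (glmnet parameterization)."""
    n = x.shape[0]
    c = 1.0 / (n * lam)
    model = LogisticRegression(
        l1_ratio=1.0, C=c, solver="liblinear", fit_intercept=True,
        tol=1e-8, max_iter=2000, random_state=0,
    )
    model.fit(x, y)
    return model.coef_[0].copy(), float(model.intercept_[0])


def lasso_cv(
    study: ExpressionStudy,
    group1: str,
    group2: str,
    n_folds: int = 10,
    seed: int = 0,
    n_lambda: int = N_LAMBDA,
) -> RegularizationPath:
    """L1-penalized logistic path with stratified CV on binomial deviance.

    ``group1`` is coded 1, ``group2`` 0.  Features are standardized
    internally; reported coefficients are on the original scale.
    lambda_1se is the largest lambda whose mean CV deviance is within one
    standard error of the minimum.  If folds cannot keep both classes the
    fold count is reduced (minimum 3); with a single usable feature an
    unpenalized fit is used and flagged.
    """
    idx1, idx2 = study.samples_in(group1), study.samples_in(group2)
    x = study.matrix[:, np.concatenate([idx1, idx2])].T
    y = np.concatenate([np.ones(idx1.size), np.zeros(idx2.size)])
    features = study.feature_ids

    mu, sd = x.mean(axis=0), x.std(axis=0, ddof=0)
    usable = sd > 0
    if usable.sum() == 0:
        raise ValueError("no feature varies across samples")
    xs = (x[:, usable] - mu[usable]) / sd[usable]
    used_features = tuple(f for f, u in zip(features, usable) if u)

    n = len(y)
    n_min_class = int(min(y.sum(), n - y.sum()))
    folds = min(n_folds, n_min_class)
    if folds < n_folds:
        warnings.warn(
            f"reduced folds from {n_folds} to {folds} to keep both classes "
            "in every fold", stacklevel=2)
    if folds < 3:
        raise ValueError("need at least 3 samples in the smaller class")

    if xs.shape[1] == 1:
        log.warning("single usable feature: falling back to unpenalized fit")
        model = LogisticRegression(C=np.inf, max_iter=2000)
        model.fit(xs, y)
        beta = np.zeros(len(features))
        beta[np.flatnonzero(usable)[0]] = model.coef_[0][0] / sd[usable][0]
        lam = np.array([0.0])
        return RegularizationPath(
            lambdas=lam, coef_matrix=beta[None, :],
            intercepts=np.array([float(model.intercept_[0])]),
            cv_mean=np.array([np.nan]), cv_se=np.array([np.nan]),
            lambda_min=0.0, lambda_1se=0.0,
            panel_min=used_features, panel_1se=used_features,
            feature_ids=tuple(features), fallback_unpenalized=True,
        )

    ybar = y.mean()
    lambda_max = float(np.max(np.abs(xs.T @ (y - ybar))) / n)
    lambdas = np.geomspace(lambda_max, lambda_max * LAMBDA_MIN_RATIO, n_lambda)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(xs, y))
    losses = np.empty((len(lambdas), folds))
    for fi, (tr, te) in enumerate(splits):
        for li, lam in enumerate(lambdas):
            beta, b0 = _fit_l1(xs[tr], y[tr], lam)
            eta = xs[te] @ beta + b0
            losses[li, fi] = _deviance(y[te], 1.0 / (1.0 + np.exp(-eta)))
    cv_mean = losses.mean(axis=1)
    cv_se = losses.std(axis=1, ddof=1) / np.sqrt(folds)

    i_min = int(np.argmin(cv_mean))
    lambda_min = float(lambdas[i_min])
    threshold = cv_mean[i_min] + cv_se[i_min]
    ok = np.flatnonzero(cv_mean <= threshold)
    i_1se = int(ok.min())  # lambdas descend, so the smallest index = largest lambda
    lambda_1se = float(lambdas[i_1se])

    coef = np.zeros((len(lambdas), len(features)))
    intercepts = np.empty(len(lambdas))
    for li, lam in enumerate(lambdas):
        beta_s, b0 = _fit_l1(xs, y, lam)
        beta = np.zeros(len(features))
        beta[usable] = beta_s / sd[usable]
        coef[li] = beta
        intercepts[li] = b0 - float((beta[usable] * mu[usable]).sum())

    def panel(i: int) -> tuple[str, ...]:
        nz = np.flatnonzero(coef[i] != 0)
        order = nz[np.argsort(-np.abs(coef[i][nz]), kind="stable")]
        return tuple(features[j] for j in order)

    return RegularizationPath(
        lambdas=lambdas, coef_matrix=coef, intercepts=intercepts,
        cv_mean=cv_mean, cv_se=cv_se,
        lambda_min=lambda_min, lambda_1se=lambda_1se,
        panel_min=panel(i_min), panel_1se=panel(i_1se),
        feature_ids=tuple(features),
    )


def mann_whitney_auc(pos: Sequence[float], neg: Sequence[float]) -> float:
    """AUC = (wins + 0.5 * ties) / (n_pos * n_neg)."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = pos[:, None] - neg[None, :]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (pos.size * neg.size))


def _roc_points(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-scores, kind="stable")
    scores, labels = scores[order], labels[order]
    tps = np.cumsum(labels)
    fps = np.cumsum(1 - labels)
    # collapse tied thresholds
    distinct = np.r_[np.flatnonzero(np.diff(scores)), scores.size - 1]
    tpr = np.r_[0.0, tps[distinct] / pos.size]
    fpr = np.r_[0.0, fps[distinct] / neg.size]
    return fpr, tpr


def per_gene_auc(
    study: ExpressionStudy,
    gene: str,
    group_pos: str,
    group_neg: str,
    p_adj: float | None = None,
) -> RocResult:
    """ROC of one gene's expression as a score for group_pos vs group_neg."""
    vals = study.values(gene)
    pos = vals[study.samples_in(group_pos)]
    neg = vals[study.samples_in(group_neg)]
    if np.all(pos == pos[0]) and np.all(neg == neg[0]) and pos[0] == neg[0]:
        log.warning("gene %s is constant in both groups; AUC set to 0.5", gene)
        return RocResult(auc=0.5, fpr=np.array([0.0, 1.0]),
                         tpr=np.array([0.0, 1.0]), p_adj=p_adj)
    fpr, tpr = _roc_points(pos, neg)
    return RocResult(auc=mann_whitney_auc(pos, neg), fpr=fpr, tpr=tpr,
                     p_adj=p_adj)


def diagnostic_gate(
    study: ExpressionStudy,
    genes: Sequence[str],
    group_pos: str,
    group_neg: str,
    p_adj_by_gene: dict[str, float],
    auc_cut: float = 0.9,
    padj_cut: float = 0.003,
) -> list[str]:
    """Genes with AUC > auc_cut and adjusted p < padj_cut, AUC-descending.

    Both comparisons are strict; genes without an adjusted p are skipped.
    """
    passed = []
    for g in genes:
        if g not in p_adj_by_gene:
            continue
        roc = per_gene_auc(study, g, group_pos, group_neg)
        if roc.auc > auc_cut and p_adj_by_gene[g] < padj_cut:
            passed.append((roc.auc, g))
    passed.sort(key=lambda t: (-t[0], t[1]))
    return [g for _, g in passed]
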