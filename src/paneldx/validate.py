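"""Small-sample predictive validation.

Two complementary procedures for tiny, imbalanced cohorts:

* nested cross-validation with inner t-test feature selection and
  Firth-penalized logistic regression (finite estimates under separation);
* a safe stratified 0.632+ bootstrap of a PCA + ridge-logistic classifier
  with a matched stratified permutation null, yielding an optimism-corrected
  AUC, empirical p-value, confidence interval and Cohen's d.

"Safe" means every resample is screened: both classes must be present in
training and out-of-bag sets, the training set needs >= 2 samples per class,
and inner 3-fold stratified CV must be feasible; failing draws are rejected
and redrawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .dex import bh_adjust
from .io import ExpressionStudy
from .select import RocResult, _roc_points, mann_whitney_auc

__all__ = [
    "FirthModel",
    "NestedCvResult",
    "Boot632Summary",
    "ValidationReport",
    "firth_fit",
    "nested_cv_firth",
    "boot632_validate",
    "cohens_d",
    "auc_632plus",
]

log = logging.getLogger(__name__)

GAMMA_NO_INFO = 0.5  # no-information error rate on the error = 1 - AUC scale
MAX_REDRAWS = 50


@dataclass(frozen=True)
class FirthModel:
    coefficients: np.ndarray  # intercept first
    converged: bool
    n_iter: int
    hat_diagonals: np.ndarray

    def predict_proba(self, design: np.ndarray) -> np.ndarray:
        eta = np.asarray(design, dtype=float) @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class NestedCvResult:
    fold_assignments: np.ndarray
    selected_genes_per_fold: tuple[tuple[str, ...], ...]
    oof_scores: np.ndarray
    labels: np.ndarray
    sample_ids: tuple[str, ...]
    roc: RocResult


@dataclass(frozen=True)
class BootIteration:
    apparent_auc: float
    oob_auc: float
    auc_632plus: float
    n_components: int
    accepted: bool


@dataclass(frozen=True)
class Boot632Summary:
    iterations: tuple[BootIteration, ...]
    oob_mean: float
    oob_median: float
    ci95: tuple[float, float]
    mean_632plus: float
    median_632plus: float
    n_accepted: int


@dataclass(frozen=True)
class ValidationReport:
    boot: Boot632Summary
    perm_aucs: np.ndarray
    empirical_p: float
    cohens_d: float
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression
# ---------------------------------------------------------------------------

def firth_fit(
    design: np.ndarray,
    labels: Sequence[int],
    max_iter: int = 100,
    tol: float = 1e-8,
) -> FirthModel:
    """Maximize the Jeffreys-penalized logistic likelihood by Newton steps.

    ``design`` is samples x features *without* an intercept column; one is
    prepended internally.  The score is modified per Firth:
    ``U*_j = sum_i (y_i - pi_i + h_i (1/2 - pi_i)) x_ij`` with h_i the
    diagonal of the weighted hat matrix, which keeps estimates finite even
    under complete separation.  Step-halving guards each Newton update.
    """
    x = np.asarray(design, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(labels, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    n = x.shape[0]
    xd = np.column_stack([np.ones(n), x])
    p = xd.shape[1]
    if np.linalg.matrix_rank(xd) < p:
        # identify offending columns by greedy rank check
        bad = []
        for j in range(1, p):
            cols = [0] + [c for c in range(1, p) if c != j]
            if np.linalg.matrix_rank(xd[:, cols]) == np.linalg.matrix_rank(xd):
                bad.append(j - 1)
        raise ValueError(f"rank-deficient design; collinear feature columns {bad}")

    def penalized_loglik(beta):
        eta = xd @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        pi = np.clip(pi, 1e-12, 1 - 1e-12)
        ll = float(y @ np.log(pi) + (1 - y) @ np.log1p(-pi))
        w = pi * (1 - pi)
        info = xd.T @ (xd * w[:, None])
        sign, logdet = np.linalg.slogdet(info)
        return ll + 0.5 * logdet if sign > 0 else -np.inf

    beta = np.zeros(p)
    converged = False
    it = 0
    h = np.zeros(n)
    for it in range(1, max_iter + 1):
        eta = xd @ beta
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = pi * (1 - pi)
        info = xd.T @ (xd * w[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat diagonal of the weighted projection
        h = np.einsum("ij,jk,ik->i", xd * w[:, None], info_inv, xd)
        score = xd.T @ (y - pi + h * (0.5 - pi))
        if np.max(np.abs(score)) < tol:
            converged = True
            break
        step = info_inv @ score
        ll0 = penalized_loglik(beta)
        factor = 1.0
        for _ in range(20):
            if penalized_loglik(beta + factor * step) >= ll0 - 1e-12:
                break
            factor /= 2.0
        beta = beta + factor * step
    return FirthModel(coefficients=beta, converged=converged, n_iter=it,
                      hat_diagonals=h)


# ---------------------------------------------------------------------------
# nested CV with Firth models
# ---------------------------------------------------------------------------

def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold index per sample; classes spread as evenly as possible."""
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(idx.size)]
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def nested_cv_firth(
    study: ExpressionStudy,
    genes: Sequence[str],
    group_pos: str,
    group_neg: str,
    outer_folds: int = 5,
    top_m: int = 5,
    seed: int = 0,
    adj_p_gate: float = 0.05,
) -> NestedCvResult:
    """Nested CV: per-fold Welch t selection, Firth fit, pooled OOF ROC.

    In each outer fold the candidate genes are tested (Welch t) on the
    training samples only, BH-adjusted, and the ``top_m`` by adjusted p
    (ties by raw p then gene id) become the model features.  When fewer than
    ``top_m`` genes pass ``adj_p_gate`` a warning is logged and the top_m
    best are used anyway.  Out-of-fold probabilities are pooled into one ROC.
    """
    genes = list(genes)
    sub = study.subset_features(genes)
    ipos, ineg = study.samples_in(group_pos), study.samples_in(group_neg)
    keep = np.concatenate([ipos, ineg])
    x = sub.matrix[:, keep].T  # samples x genes
    y = np.concatenate([np.ones(ipos.size), np.zeros(ineg.size)])
    sample_ids = tuple(study.sample_ids[i] for i in keep)

    rng = np.random.default_rng(seed)
    folds = None
    for attempt in range(10):
        cand = _stratified_folds(y, outer_folds, rng)
        ok = all(
            len(np.unique(y[cand != f])) == 2 and np.any(cand == f)
            for f in range(outer_folds)
        )
        if ok:
            folds = cand
            break
    if folds is None:
        raise ValueError("could not stratify outer folds with both classes")

    oof = np.full(len(y), np.nan)
    selected: list[tuple[str, ...]] = []
    for f in range(outer_folds):
        tr, te = folds != f, folds == f
        xtr, ytr = x[tr], y[tr]
        stats_rows = []
        for j, g in enumerate(genes):
            a, b = xtr[ytr == 1, j], xtr[ytr == 0, j]
            if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
                p = 1.0
            else:
                p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
            stats_rows.append((g, j, p))
    # columns: gene, index, raw p
        praw = np.array([r[2] for r in stats_rows])
        padj = bh_adjust(praw)
        ranked = sorted(
            range(len(genes)), key=lambda i: (padj[i], praw[i], genes[i])
        )
        n_pass = int(np.sum(padj < adj_p_gate))
        if n_pass < top_m:
            log.warning(
                "fold %d: only %d genes pass adj p < %.3g; using top %d anyway",
                f, n_pass, adj_p_gate, top_m)
        chosen_idx = ranked[: min(top_m, len(genes))]
        chosen = tuple(genes[i] for i in chosen_idx)
        selected.append(chosen)

        mu = xtr[:, chosen_idx].mean(axis=0)
        sd = xtr[:, chosen_idx].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        ztr = (xtr[:, chosen_idx] - mu) / sd
        zte = (x[te][:, chosen_idx] - mu) / sd
        model = firth_fit(ztr, ytr)
        oof[te] = model.predict_proba(np.column_stack([np.ones(zte.shape[0]), zte]))

    assert not np.any(np.isnan(oof))
    fpr, tpr = _roc_points(oof[y == 1], oof[y == 0])
    roc = RocResult(auc=mann_whitney_auc(oof[y == 1], oof[y == 0]),
                    fpr=fpr, tpr=tpr)
    return NestedCvResult(
        fold_assignments=folds,
        selected_genes_per_fold=tuple(selected),
        oof_scores=oof,
        labels=y,
        sample_ids=sample_ids,
        roc=roc,
    )


# ---------------------------------------------------------------------------
# ridge logistic IRLS (used inside the bootstrap; small dense problems)
# ---------------------------------------------------------------------------

def _ridge_logistic(
    x: np.ndarray, y: np.ndarray, lam: float, max_iter: int = 50, tol: float = 1e-8
) -> np.ndarray:
    """Newton solver for L2-penalized logistic regression.

    Intercept (first coefficient) unpenalized.  Returns the coefficient
    vector for the design [1 | x].
    """
    n = x.shape[0]
    xd = np.column_stack([np.ones(n), x])
    p = xd.shape[1]
    pen = lam * np.eye(p)
    pen[0, 0] = 0.0
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = np.clip(xd @ beta, -30, 30)
        pi = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(pi * (1 - pi), 1e-10)
        grad = xd.T @ (y - pi) - pen @ beta
        hess = xd.T @ (xd * w[:, None]) + pen
        step = np.linalg.solve(hess, grad)
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def _deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log1p(-p)))


def _inner_cv_lambda(
    x: np.ndarray, y: np.ndarray, lambdas: np.ndarray, rng: np.random.Generator
) -> float:
    folds = _stratified_folds(y, 3, rng)
    losses = np.zeros(len(lambdas))
    for f in range(3):
        tr, te = folds != f, folds == f
        for li, lam in enumerate(lambdas):
            beta = _ridge_logistic(x[tr], y[tr], lam)
            eta = np.clip(np.column_stack([np.ones(te.sum()), x[te]]) @ beta, -30, 30)
            losses[li] += _deviance(y[te], 1.0 / (1.0 + np.exp(-eta)))
    return float(lambdas[int(np.argmin(losses))])


def auc_632plus(apparent_auc: float, oob_auc: float,
                gamma: float = GAMMA_NO_INFO) -> float:
    """0.632+ correction on the error scale (err = 1 - AUC).

    err_oob is clipped at gamma; the relative overfitting rate
    R = (err_oob' - err_app) / (gamma - err_app) is clipped to [0, 1]
    (0 when the denominator is <= 0); weight w = 0.632 / (1 - 0.368 R).
    """
    err_app = 1.0 - apparent_auc
    err_oob = min(1.0 - oob_auc, gamma)
    denom = gamma - err_app
    if denom <= 0:
        r = 0.0
    else:
        r = min(1.0, max(0.0, (err_oob - err_app) / denom))
    w = 0.632 / (1.0 - 0.368 * r)
    err = (1.0 - w) * err_app + w * err_oob
    return 1.0 - err


def _safe_draw(
    y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, bool]:
    """One stratified 63.2% with-replacement draw plus safety screening.

    Returns (train indices with multiplicity, OOB indices, accepted).
    Safety: both classes in train and OOB; >= 2 per class in train; inner
    3-fold stratified CV feasible (>= 3 training rows per class, so every
    inner training split keeps >= 2 per class).
    """
    train_parts = []
    drawn: set[int] = set()
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        n_draw = int(round(0.632 * idx.size))
        if n_draw == 0:
            return np.empty(0, int), np.empty(0, int), False
        pick = rng.choice(idx, size=n_draw, replace=True)
        train_parts.append(pick)
        drawn.update(pick.tolist())
    train = np.concatenate(train_parts)
    oob = np.array([i for i in range(len(y)) if i not in drawn], dtype=int)
    ytr = y[train]
    ok = (
        len(np.unique(ytr)) == 2
        and len(oob) > 0
        and len(np.unique(y[oob])) == 2
        and min((ytr == 0).sum(), (ytr == 1).sum()) >= 3
    )
    return train, oob, ok


def _pca_ridge_iteration(
    x: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    oob: np.ndarray,
    lambdas: np.ndarray,
    rng: np.random.Generator,
    max_components: int = 3,
    var_target: float = 0.95,
) -> BootIteration:
    """Fit PCA + ridge on the training rows, score train and OOB AUCs."""
    xtr, ytr = x[train], y[train]
    mu = xtr.mean(axis=0)
    sd = xtr.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    ztr = (xtr - mu) / sd
    zoob = (x[oob] - mu) / sd

    u, s, vt = np.linalg.svd(ztr - ztr.mean(axis=0), full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 0:
        n_comp = 1
    else:
        frac = np.cumsum(var) / total
        n_comp = int(np.searchsorted(frac, var_target) + 1)
    n_comp = max(1, min(n_comp, max_components, int((s > 1e-10).sum()) or 1))
    basis = vt[:n_comp].T
    center = ztr.mean(axis=0)
    ctr = (ztr - center) @ basis
    coob = (zoob - center) @ basis

    lam = _inner_cv_lambda(ctr, ytr, lambdas, rng)
    beta = _ridge_logistic(ctr, ytr, lam)
    p_tr = 1.0 / (1.0 + np.exp(-np.clip(
        np.column_stack([np.ones(len(ctr)), ctr]) @ beta, -30, 30)))
    p_oob = 1.0 / (1.0 + np.exp(-np.clip(
        np.column_stack([np.ones(len(coob)), coob]) @ beta, -30, 30)))
    app = mann_whitney_auc(p_tr[ytr == 1], p_tr[ytr == 0])
    yoob = y[oob]
    oob_auc = mann_whitney_auc(p_oob[yoob == 1], p_oob[yoob == 0])
    return BootIteration(
        apparent_auc=app,
        oob_auc=oob_auc,
        auc_632plus=auc_632plus(app, oob_auc),
        n_components=n_comp,
        accepted=True,
    )


def boot632_validate(
    study: ExpressionStudy,
    panel: Sequence[str],
    group_pos: str,
    group_neg: str,
    B: int = 200,
    P: int = 200,
    seed: int = 0,
    n_ridge_lambdas: int = 50,
) -> ValidationReport:
    """Safe stratified 0.632+ bootstrap with matched permutation null.

    For each of B iterations a stratified 63.2% with-replacement draw is
    screened by the safety constraints (redrawn up to 50 times, else
    recorded unaccepted), then a PCA (>=95% variance, <=3 components) +
    ridge-logistic model (lambda by inner 3-fold CV on deviance) yields
    apparent and OOB AUCs and the 0.632+-corrected AUC.  P stratified label
    permutations each run the identical pipeline for one accepted draw; the
    empirical p is the fraction of permutation AUCs >= the median bootstrap
    0.632+ AUC.  The 95% CI comes from accepted OOB AUC quantiles and
    Cohen's d compares the bootstrap and permutation 0.632+ distributions.
    """
    panel = list(panel)
    available = [g for g in panel if g in study.feature_ids]
    missing = sorted(set(panel) - set(available))
    if missing:
        log.warning("panel genes absent from expression features: %s", missing)
    if not available:
        raise ValueError("no panel gene is present in the expression features")
    if B < 50 or P < 50:
        raise ValueError("B and P must be >= 50")

    sub = study.subset_features(available)
    ipos, ineg = study.samples_in(group_pos), study.samples_in(group_neg)
    keep = np.concatenate([ipos, ineg])
    x = sub.matrix[:, keep].T  # samples x genes
    y = np.concatenate([np.ones(ipos.size), np.zeros(ineg.size)])

    # feasibility at cohort level: a compliant draw must be possible
    for cls, name in ((1.0, group_pos), (0.0, group_neg)):
        n_c = int((y == cls).sum())
        if int(round(0.632 * n_c)) < 3:
            raise ValueError(
                f"group {name!r} has {n_c} samples; a 63.2% draw cannot hold "
                ">=3 training samples per class (inner 3-fold CV infeasible)")

    rng = np.random.default_rng(seed)
    lambdas = np.geomspace(1e-3, 1e3, n_ridge_lambdas)

    def one_accepted(yy: np.ndarray) -> BootIteration:
        for _ in range(MAX_REDRAWS):
            train, oob, ok = _safe_draw(yy, rng)
            if ok:
                return _pca_ridge_iteration(x, yy, train, oob, lambdas, rng)
        return BootIteration(np.nan, np.nan, np.nan, 0, accepted=False)

    iterations = [one_accepted(y) for _ in range(B)]
    accepted = [it for it in iterations if it.accepted]
    if not accepted:
        raise ValueError("no bootstrap iteration satisfied the safety checks")
    oob_aucs = np.array([it.oob_auc for it in accepted])
    plus = np.array([it.auc_632plus for it in accepted])
    boot = Boot632Summary(
        iterations=tuple(iterations),
        oob_mean=float(oob_aucs.mean()),
        oob_median=float(np.median(oob_aucs)),
        ci95=(float(np.quantile(oob_aucs, 0.025)),
              float(np.quantile(oob_aucs, 0.975))),
        mean_632plus=float(plus.mean()),
        median_632plus=float(np.median(plus)),
        n_accepted=len(accepted),
    )

    perm_aucs = []
    for _ in range(P):
        y_perm = y[rng.permutation(len(y))]
        it = one_accepted(y_perm)
        if it.accepted:
            perm_aucs.append(it.auc_632plus)
    perm = np.array(perm_aucs)
    if perm.size == 0:
        raise ValueError("no permutation iteration satisfied the safety checks")
    empirical_p = float(np.mean(perm >= boot.median_632plus))
    d = cohens_d(plus, perm)
    return ValidationReport(
        boot=boot,
        perm_aucs=perm,
        empirical_p=empirical_p,
        cohens_d=d,
        config={"B": B, "P": P, "seed": seed, "panel": available,
                "group_pos": group_pos, "group_neg": group_neg,
                "n_permutations_accepted": int(perm.size)},
    )


def cohens_d(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """(mean_a - mean_b) / pooled SD; signed infinity when the SD is 0."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need >= 2 values")
    diff = a.mean() - b.mean()
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled == 0:
        log.warning("zero pooled SD in cohens_d; returning signed infinity")
        return float(np.sign(diff) * np.inf) if diff != 0 else 0.0
    return float(diff / np.sqrt(pooled))
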