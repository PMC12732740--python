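"""Two-group differential expression.

Implements log2 fold changes, ordinary / Welch / empirical-Bayes moderated t
statistics, exact and normal-approximation Wilcoxon rank-sum tests,
Benjamini-Hochberg adjustment, the fold-change/p screen and tidy summary
tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionStudy

__all__ = [
    "DexRecord",
    "RankTestResult",
    "moderated_t",
    "ordinary_t",
    "welch_t",
    "wilcoxon_rank_sum",
    "exact_u_distribution",
    "bh_adjust",
    "screen_degs",
    "dex_summary_tables",
]

log = logging.getLogger(__name__)

EXACT_MAX_N = 30  # largest n1+n2 for which the exact null is enumerated
D0_CAP = 1e6  # prior df above this treated as infinite


@dataclass(frozen=True)
class DexRecord:
    gene: str
    log2fc: float
    t_stat: float
    p_raw: float
    p_adj: float
    test: str


@dataclass(frozen=True)
class RankTestResult:
    u_stat: float
    n1: int
    n2: int
    p_two_sided: float
    method: str  # "exact" | "normal_tie_corrected"


# ---------------------------------------------------------------------------
# exact Mann-Whitney null distribution
# ---------------------------------------------------------------------------

def exact_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of group labelings realizing each U value, U = 0 .. n1*n2.

    count[u] is the number of partitions of u into at most n1 parts, each
    part at most n2 (the classical generating-function recursion for the
    Mann-Whitney null).  The counts sum to C(n1+n2, n1).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    c = np.zeros(n1 * n2 + 1, dtype=object)
    c[0] = 1
    # multiply the Gaussian-binomial product one factor at a time
    for i in range(1, n1 + 1):
        new = np.zeros_like(c)
        for u in range(n1 * n2 + 1):
            v = c[u]
            if u - i >= 0:
                v += new[u - i]
            if u - i - n2 >= 0:
                v -= c[u - i - n2]
            new[u] = v
        c = new
    assert sum(c) == math.comb(n1 + n2, n1)
    return c


def exact_u_pvalue(u: int, n1: int, n2: int) -> float:
    """Two-sided exact p at U=u: doubled smaller tail, capped at 1."""
    counts = exact_u_distribution(n1, n2)
    total = math.comb(n1 + n2, n1)
    lo = int(sum(counts[: u + 1]))
    hi = int(sum(counts[u:]))
    return min(1.0, 2 * min(lo, hi) / total)


def wilcoxon_rank_sum(
    values1: Sequence[float],
    values2: Sequence[float],
    exact_max_n: int = EXACT_MAX_N,
) -> RankTestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact enumerated null when there are no cross-group ties and
    n1+n2 <= ``exact_max_n``; otherwise a normal approximation with
    tie-corrected variance and a 0.5 continuity correction.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups need at least one value")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    has_ties = len(np.unique(combined)) < n1 + n2
    if not has_ties and n1 + n2 <= exact_max_n:
        p = exact_u_pvalue(int(round(u1)), n1, n2)
        return RankTestResult(u_stat=float(u1), n1=n1, n2=n2,
                              p_two_sided=p, method="exact")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return RankTestResult(u_stat=float(u1), n1=n1, n2=n2,
                              p_two_sided=1.0, method="normal_tie_corrected")
    z = (abs(u1 - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    p = min(1.0, 2 * stats.norm.sf(z))
    return RankTestResult(u_stat=float(u1), n1=n1, n2=n2,
                          p_two_sided=p, method="normal_tie_corrected")


# ---------------------------------------------------------------------------
# t statistics
# ---------------------------------------------------------------------------

def _group_matrices(study: ExpressionStudy, group1: str, group2: str):
    x1 = study.matrix[:, study.samples_in(group1)]
    x2 = study.matrix[:, study.samples_in(group2)]
    return x1, x2


def _pooled_t(x1: np.ndarray, x2: np.ndarray):
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    df = n1 + n2 - 2
    ss = x1.var(axis=1, ddof=1) * (n1 - 1) + x2.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    se_factor = 1.0 / n1 + 1.0 / n2
    return m1 - m2, s2, df, se_factor


def _records(study, lfc, tstat, p, test) -> list[DexRecord]:
    padj = bh_adjust(p)
    return [
        DexRecord(gene=g, log2fc=float(lfc[i]), t_stat=float(tstat[i]),
                  p_raw=float(p[i]), p_adj=float(padj[i]), test=test)
        for i, g in enumerate(study.feature_ids)
    ]


def ordinary_t(study: ExpressionStudy, group1: str, group2: str) -> list[DexRecord]:
    """Equal-variance two-sample t test per feature."""
    x1, x2 = _group_matrices(study, group1, group2)
    lfc, s2, df, se_factor = _pooled_t(x1, x2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2 * se_factor)
    t = np.where(np.isfinite(t), t, 0.0)
    p = 2 * stats.t.sf(np.abs(t), df)
    return _records(study, lfc, t, p, "ordinary_t")


def welch_t(study: ExpressionStudy, group1: str, group2: str) -> list[DexRecord]:
    """Unequal-variance (Welch) two-sample t test per feature."""
    x1, x2 = _group_matrices(study, group1, group2)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 samples")
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1) / n1, x2.var(axis=1, ddof=1) / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    t = np.where(np.isfinite(t), t, 0.0)
    df = np.where(np.isfinite(df), df, n1 + n2 - 2)
    p = 2 * stats.t.sf(np.abs(t), df)
    return _records(study, lfc, t, p, "welch_t")


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Invert the trigamma function by Newton iteration (vectorized)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # starting value, good for all x > 0
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed sample variances.

    Returns (d0, s0_squared): prior degrees of freedom and prior variance,
    estimated from the mean and variance of log sample variances.  d0 may be
    ``inf`` when the observed spread is no larger than expected from chance.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.median(s2[ok])) if ok.any() else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + math.log(df / 2)
    mean_e = e.mean()
    var_e = e.var(ddof=1) * (1 + 1 / len(e))  # small-sample inflation guard
    excess = var_e - special.polygamma(1, df / 2)
    if excess <= 0:
        d0 = math.inf
        s0_sq = math.exp(mean_e)
    else:
        d0 = float(2 * _trigamma_inverse(np.array([excess]))[0])
        if d0 > D0_CAP:
            d0 = math.inf
            s0_sq = math.exp(mean_e)
        else:
            s0_sq = math.exp(mean_e + special.digamma(d0 / 2) - math.log(d0 / 2))
    return d0, float(s0_sq)


def moderated_t(
    study: ExpressionStudy,
    group1: str,
    group2: str,
    d0_override: float | None = None,
) -> list[DexRecord]:
    """Empirical-Bayes moderated t test per feature.

    Per-gene variances are shrunk toward a common prior:
    ``s~2 = (d0*s0^2 + df*s^2) / (d0 + df)``, and the t statistic is referred
    to a t distribution on ``d0 + df`` degrees of freedom.  ``d0_override=0``
    disables shrinkage (reduces to the ordinary t).
    """
    x1, x2 = _group_matrices(study, group1, group2)
    lfc, s2, df, se_factor = _pooled_t(x1, x2)
    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[s2 > 0])) if np.any(s2 > 0) else 1.0
    else:
        d0, s0_sq = fit_f_dist(s2, df)
    if math.isinf(d0):
        log.info("variance prior df diverged; shrinking all variances to s0^2")
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / np.sqrt(s2_tilde * se_factor)
    t = np.where(np.isfinite(t), t, 0.0)
    if math.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    return _records(study, lfc, t, p, "moderated_t")


def wilcoxon_dex(study: ExpressionStudy, group1: str, group2: str) -> list[DexRecord]:
    """Per-feature Wilcoxon rank-sum comparison between two groups."""
    x1, x2 = _group_matrices(study, group1, group2)
    lfc = x1.mean(axis=1) - x2.mean(axis=1)
    results = [wilcoxon_rank_sum(x1[i], x2[i]) for i in range(study.n_features)]
    p = np.array([r.p_two_sided for r in results])
    padj = bh_adjust(p)
    return [
        DexRecord(
            gene=g,
            log2fc=float(lfc[i]),
            t_stat=float(results[i].u_stat),
            p_raw=float(p[i]),
            p_adj=float(padj[i]),
            test="wilcoxon_exact" if results[i].method == "exact" else "wilcoxon_normal",
        )
        for i, g in enumerate(study.feature_ids)
    ]


# ---------------------------------------------------------------------------
# multiple testing and screening
# ---------------------------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def screen_degs(
    records: Sequence[DexRecord], lfc_cut: float = 1.0, p_cut: float = 0.05
) -> set[str]:
    """Genes passing the strict |log2FC| > lfc_cut and raw p < p_cut gate."""
    return {r.gene for r in records if abs(r.log2fc) > lfc_cut and r.p_raw < p_cut}


def dex_summary_tables(
    records: Sequence[DexRecord], study: ExpressionStudy, top_n: int = 30
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Volcano table (all genes) and z-scored heatmap table of the top genes.

    The heatmap covers the ``top_n`` genes by |log2FC| (ties by gene id),
    each row standardized to mean 0, SD 1 across samples.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    volcano = pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "log2fc": [r.log2fc for r in records],
            "neg_log10_p": [-math.log10(r.p_raw) if r.p_raw > 0 else math.inf
                            for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
        }
    )
    ranked = sorted(records, key=lambda r: (-abs(r.log2fc), r.gene))
    chosen = [r.gene for r in ranked[: min(top_n, len(ranked))]]
    sub = study.subset_features(chosen)
    z = sub.matrix - sub.matrix.mean(axis=1, keepdims=True)
    sd = z.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = z / sd[:, None]
    heat = pd.DataFrame(z, index=chosen, columns=list(study.sample_ids))
    return volcano, heat


def records_to_frame(records: Sequence[DexRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "log2fc": [r.log2fc for r in records],
            "t": [r.t_stat for r in records],
            "p_raw": [r.p_raw for r in records],
            "p_adj": [r.p_adj for r in records],
            "test": [r.test for r in records],
        }
    )
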