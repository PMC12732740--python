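"""Preranked gene-set enrichment and hypergeometric over-representation."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dex import bh_adjust
from .io import GeneSetCollection

__all__ = [
    "RankedList",
    "EnrichmentRecord",
    "enrichment_score",
    "gsea_preranked",
    "hypergeom_ora",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedList:
    """Genes sorted by a descending metric; ties keep input order."""

    genes: tuple[str, ...]
    metric: np.ndarray

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        metric = np.asarray(self.metric, dtype=float)
        if len(genes) != metric.size:
            raise ValueError("genes and metric lengths differ")
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene ids in ranked list")
        if np.any(np.diff(metric) > 1e-12):
            raise ValueError("metric must be non-increasing")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "metric", metric)

    @classmethod
    def from_scores(cls, scores: dict[str, float]) -> "RankedList":
        items = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(
            genes=tuple(k for k, _ in items),
            metric=np.array([v for _, v in items]),
        )


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    es: float
    nes: float
    p_raw: float
    fdr_q: float
    size: int


def _running_sum(metric: np.ndarray, hit: np.ndarray, weight: float) -> np.ndarray:
    """Weighted KS-like running sum over the ranked list."""
    n = metric.size
    n_hit = int(hit.sum())
    w = np.abs(metric) ** weight
    hit_mass = np.where(hit, w, 0.0)
    total = hit_mass.sum()
    if total == 0:  # all hit metrics zero: fall back to uniform increments
        hit_mass = hit.astype(float)
        total = hit_mass.sum()
    steps = hit_mass / total - (~hit) / (n - n_hit)
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList, gene_set: Sequence[str] | set[str], weight: float = 1.0
) -> tuple[float, np.ndarray]:
    """Enrichment score and its running-sum profile for one gene set.

    Hits increment proportionally to |metric|^weight (normalized to total 1);
    misses decrement 1/(N - n_set).  The score is the running sum's maximum
    deviation from zero, signed.
    """
    members = set(gene_set)
    hit = np.fromiter((g in members for g in ranked.genes), dtype=bool,
                      count=len(ranked.genes))
    if not hit.any():
        raise ValueError("gene set does not intersect the ranked list")
    if hit.all():
        raise ValueError("gene set covers the whole ranked list")
    profile = _running_sum(ranked.metric, hit, weight)
    i = int(np.argmax(np.abs(profile)))
    return float(profile[i]), profile


def _es_only(metric: np.ndarray, hit: np.ndarray, weight: float) -> float:
    profile = _running_sum(metric, hit, weight)
    return float(profile[np.argmax(np.abs(profile))])


def gsea_preranked(
    ranked: RankedList,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    min_size: int = 5,
    max_size: int = 500,
    seed: int = 0,
    weight: float = 1.0,
) -> list[EnrichmentRecord]:
    """Preranked GSEA with a random-gene-set permutation null.

    For each candidate set size the null is built by drawing ``n_perm``
    random sets of that size from the ranked universe.  NES divides ES by the
    mean |null ES| of the same sign; p_raw is the same-sign tail fraction;
    fdr_q is the GSEA-style ratio of tail fractions over the pooled
    same-sign NES values.  Results are sorted by NES descending.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    universe = list(ranked.genes)
    n = len(universe)
    index = {g: i for i, g in enumerate(universe)}

    candidates: list[tuple[str, np.ndarray]] = []
    for name in sorted(collection.sets):
        members = [g for g in collection.sets[name] if g in index]
        if not (min_size <= len(members) <= max_size) or len(members) >= n:
            continue
        hit = np.zeros(n, dtype=bool)
        hit[[index[g] for g in members]] = True
        candidates.append((name, hit))
    if not candidates:
        warnings.warn("all gene sets removed by size filters", stacklevel=2)
        return []

    # shared null per distinct set size
    sizes = sorted({int(h.sum()) for _, h in candidates})
    null_by_size: dict[int, np.ndarray] = {}
    for size in sizes:
        null = np.empty(n_perm)
        for b in range(n_perm):
            hit = np.zeros(n, dtype=bool)
            hit[rng.choice(n, size=size, replace=False)] = True
            null[b] = _es_only(ranked.metric, hit, weight)
        null_by_size[size] = null

    raw: list[tuple[str, float, float, float, int]] = []
    all_null_nes: list[np.ndarray] = []
    for name, hit in candidates:
        size = int(hit.sum())
        es = _es_only(ranked.metric, hit, weight)
        null = null_by_size[size]
        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if same_sign.size == 0 or np.mean(np.abs(same_sign)) == 0:
            nes, p = 0.0, 1.0
        else:
            denom = float(np.mean(np.abs(same_sign)))
            nes = es / denom
            p = float(np.mean(np.abs(same_sign) >= abs(es)))
        raw.append((name, es, nes, p, size))
    # pooled null NES for the FDR ratio (normalize each null draw by its
    # own sign's mean within its size stratum)
    for size in sizes:
        null = null_by_size[size]
        pos, neg = null[null >= 0], null[null < 0]
        mp = np.mean(np.abs(pos)) if pos.size else 1.0
        mn = np.mean(np.abs(neg)) if neg.size else 1.0
        nes_null = np.where(null >= 0, null / (mp or 1.0), null / (mn or 1.0))
        all_null_nes.append(nes_null)
    pooled = np.concatenate(all_null_nes)
    obs_nes = np.array([r[2] for r in raw])

    records = []
    for name, es, nes, p, size in raw:
        if nes >= 0:
            tail_null = np.mean(pooled >= nes) / max(np.mean(pooled >= 0), 1e-12)
            tail_obs = np.mean(obs_nes >= nes) / max(np.mean(obs_nes >= 0), 1e-12)
        else:
            tail_null = np.mean(pooled <= nes) / max(np.mean(pooled < 0), 1e-12)
            tail_obs = np.mean(obs_nes <= nes) / max(np.mean(obs_nes < 0), 1e-12)
        q = float(min(1.0, tail_null / max(tail_obs, 1e-12)))
        records.append(EnrichmentRecord(set_name=name, es=float(es),
                                        nes=float(nes), p_raw=float(p),
                                        fdr_q=q, size=size))
    records.sort(key=lambda r: (-r.nes, r.set_name))
    return records


def hypergeom_ora(
    query: set[str] | Sequence[str],
    collection: GeneSetCollection,
    universe: set[str] | Sequence[str],
) -> list[EnrichmentRecord]:
    """One-sided hypergeometric over-representation per set, BH-adjusted."""
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("query gene set is empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n_uni = len(universe)
    names, pvals, esses, sizes = [], [], [], []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        if not members:
            continue
        k = len(query & members)
        # P(X >= k) for X ~ Hypergeom(N=n_uni, K=|members|, n=|query|)
        p = float(stats.hypergeom.sf(k - 1, n_uni, len(members), len(query)))
        expected = len(members) * len(query) / n_uni
        names.append(name)
        pvals.append(min(1.0, p))
        esses.append(k / expected if expected > 0 else 0.0)
        sizes.append(len(members))
    adj = bh_adjust(pvals) if pvals else np.array([])
    records = [
        EnrichmentRecord(set_name=nm, es=float(e), nes=float(e),
                         p_raw=float(p), fdr_q=float(q), size=s)
        for nm, e, p, q, s in zip(names, esses, pvals, adj, sizes)
    ]
    records.sort(key=lambda r: (r.p_raw, r.set_name))
    return records


def records_to_frame(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.set_name for r in records],
            "size": [r.size for r in records],
            "es": [r.es for r in records],
            "nes": [r.nes for r in records],
            "p_raw": [r.p_raw for r in records],
            "fdr_q": [r.fdr_q for r in records],
        }
    )
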