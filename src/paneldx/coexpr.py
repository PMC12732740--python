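"""Weighted co-expression network analysis.

Soft-threshold scan against the scale-free topology criterion, unsigned
adjacency, topological overlap, average-linkage module detection with a
static tree cut, module eigengenes (first principal component), eigengene
merging and module-trait correlation.

Divergence from the reference tooling: modules come from a static cut of the
average-linkage tree at a fixed height rather than the dynamic hybrid tree
cut; the cut height is exposed and recovery is validated on planted modules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .io import ExpressionStudy

__all__ = [
    "SoftThresholdScan",
    "ModuleDecomposition",
    "adjacency_matrix",
    "scan_soft_threshold",
    "topological_overlap",
    "detect_modules",
    "module_eigengenes",
    "merge_modules",
    "module_trait_correlation",
]

log = logging.getLogger(__name__)

GREY = "grey"
SCALE_FREE_TARGET = 0.85
N_BINS = 10


@dataclass(frozen=True)
class SoftThresholdScan:
    powers: tuple[int, ...]
    r_squared: tuple[float, ...]
    mean_connectivity: tuple[float, ...]
    chosen_power: int
    reached_target: bool


@dataclass
class ModuleDecomposition:
    """Gene -> module assignment with eigengenes and provenance."""

    assignment: dict[str, str]
    eigengenes: pd.DataFrame  # modules x samples
    merged_from: dict[str, tuple[str, ...]] = field(default_factory=dict)
    trait_correlation: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict
    )

    def genes_of(self, module: str) -> list[str]:
        return [g for g, m in self.assignment.items() if m == module]

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.index]


def adjacency_matrix(study: ExpressionStudy, power: float) -> np.ndarray:
    """Unsigned adjacency |cor|^power with zero diagonal."""
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(study.matrix)
    cor = np.nan_to_num(cor, nan=0.0)
    adj = np.abs(cor) ** power
    np.fill_diagonal(adj, 0.0)
    return adj


def _scale_free_fit(connectivity: np.ndarray) -> float:
    """Signed R^2 of log10 density(k) vs log10 k over equal-count bins.

    Bin counts are normalized by bin width so equal-count binning still
    resolves the shape of p(k).  Sign is -sign(slope), so a decaying degree
    distribution scores positively.  Returns 0.0 on degenerate input.
    """
    k = connectivity[connectivity > 0]
    if k.size < N_BINS or np.allclose(k, k[0]):
        return 0.0
    edges = np.quantile(k, np.linspace(0, 1, N_BINS + 1))
    edges = np.unique(edges)
    if edges.size < 4:
        return 0.0
    counts, _ = np.histogram(k, bins=edges)
    widths = np.diff(edges)
    # mean connectivity inside each bin as its abscissa
    which = np.clip(np.searchsorted(edges, k, side="right") - 1, 0,
                    len(counts) - 1)
    centers = np.array([
        k[which == b].mean() if np.any(which == b) else np.nan
        for b in range(len(counts))
    ])
    ok = (counts > 0) & (widths > 0) & np.isfinite(centers) & (centers > 0)
    if ok.sum() < 3:
        return 0.0
    x = np.log10(centers[ok])
    y = np.log10(counts[ok] / (k.size * widths[ok]))
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return 0.0
    slope, _, r, _, _ = stats.linregress(x, y)
    if not np.isfinite(slope) or not np.isfinite(r):
        return 0.0
    return float(-np.sign(slope) * r**2)


def scan_soft_threshold(
    study: ExpressionStudy,
    powers: Sequence[int] = tuple(range(1, 21)),
    target: float = SCALE_FREE_TARGET,
) -> SoftThresholdScan:
    """Scan candidate powers and pick the smallest reaching the fit target.

    If no power reaches the target the best-fitting power is returned and a
    fallback is logged (mirrors practice on weakly structured cohorts).
    """
    if study.n_features < 3:
        raise ValueError("need at least 3 features")
    if study.n_samples < 8:
        warnings.warn("fewer than 8 samples: correlation estimates are noisy",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(study.matrix)
    cor = np.nan_to_num(cor, nan=0.0)
    abs_cor = np.abs(cor)
    np.fill_diagonal(abs_cor, 0.0)
    fits, ks = [], []
    for beta in powers:
        adj = abs_cor**beta
        k = adj.sum(axis=1)
        fits.append(_scale_free_fit(k))
        ks.append(float(k.mean()))
    fits_arr = np.array(fits)
    reached = bool(np.any(fits_arr >= target))
    if reached:
        chosen = int(powers[int(np.argmax(fits_arr >= target))])
    else:
        chosen = int(powers[int(np.argmax(fits_arr))])
        log.info("no power reached scale-free fit %.2f; falling back to "
                 "best fit at power %d", target, chosen)
    return SoftThresholdScan(
        powers=tuple(int(p) for p in powers),
        r_squared=tuple(fits),
        mean_connectivity=tuple(ks),
        chosen_power=chosen,
        reached_target=reached,
    )


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), unit diagonal."""
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if np.max(np.abs(a - a.T)) > 1e-10:
        raise ValueError("adjacency must be symmetric")
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def module_eigengenes(
    study: ExpressionStudy, assignment: Mapping[str, str]
) -> pd.DataFrame:
    """First principal component of each module's standardized submatrix.

    Eigengenes are scaled to unit variance and sign-aligned so their
    correlation with the module's mean expression profile is non-negative.
    Grey (unassigned) genes contribute no eigengene.
    """
    modules = sorted({m for m in assignment.values() if m != GREY})
    index = {g: i for i, g in enumerate(study.feature_ids)}
    rows = []
    for module in modules:
        genes = sorted(g for g, m in assignment.items() if m == module)
        sub = _standardize_rows(study.matrix[[index[g] for g in genes]])
        if sub.shape[0] == 1:
            eig = sub[0]
        else:
            # first right singular vector of the gene-standardized matrix
            _, _, vt = np.linalg.svd(sub, full_matrices=False)
            eig = vt[0]
        sd = eig.std(ddof=0)
        eig = eig / (sd if sd > 0 else 1.0)
        mean_profile = sub.mean(axis=0)
        if np.std(mean_profile) > 0 and np.corrcoef(eig, mean_profile)[0, 1] < 0:
            eig = -eig
        rows.append(eig)
    return pd.DataFrame(rows, index=modules, columns=list(study.sample_ids))


def _label_modules(
    genes: Sequence[str], cluster_ids: np.ndarray, min_module_size: int
) -> dict[str, str]:
    """Deterministic labels: descending size, ties by first gene id."""
    clusters: dict[int, list[str]] = {}
    for g, c in zip(genes, cluster_ids):
        clusters.setdefault(int(c), []).append(g)
    keep = [
        sorted(members)
        for members in clusters.values()
        if len(members) >= min_module_size
    ]
    keep.sort(key=lambda ms: (-len(ms), ms[0]))
    assignment = {g: GREY for g in genes}
    for rank, members in enumerate(keep, start=1):
        for g in members:
            assignment[g] = f"M{rank}"
    return assignment


def detect_modules(
    study: ExpressionStudy,
    power: float,
    min_module_size: int = 20,
    cut_height: float = 0.95,
) -> ModuleDecomposition:
    """Static-cut average-linkage clustering on 1 - TOM.

    Clusters smaller than ``min_module_size`` become grey.  Labels are
    assigned by descending module size (ties by first gene id) so the result
    is invariant to gene ordering.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    adj = adjacency_matrix(study, power)
    tom = topological_overlap(adj)
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    diss = np.clip((diss + diss.T) / 2, 0.0, None)
    condensed = squareform(diss, checks=False)
    link = average(condensed)
    cluster_ids = fcluster(link, t=cut_height, criterion="distance")
    assignment = _label_modules(study.feature_ids, cluster_ids, min_module_size)
    eig = module_eigengenes(study, assignment)
    decomp = ModuleDecomposition(assignment=assignment, eigengenes=eig)
    decomp.merged_from = {m: (m,) for m in decomp.modules}
    return decomp


def merge_modules(
    study: ExpressionStudy,
    decomposition: ModuleDecomposition,
    dissimilarity_cut: float = 0.25,
) -> ModuleDecomposition:
    """Iteratively merge modules whose eigengene dissimilarity is below cut.

    Each round merges the closest qualifying pair, recomputes eigengenes,
    and repeats until no pair of eigengenes has 1 - cor < cut.  Provenance
    of original modules is kept in ``merged_from``.
    """
    assignment = dict(decomposition.assignment)
    provenance: dict[str, set[str]] = {
        m: set(decomposition.merged_from.get(m, (m,)))
        for m in decomposition.modules
    }
    while True:
        modules = sorted({m for m in assignment.values() if m != GREY})
        if len(modules) < 2:
            break
        eig = module_eigengenes(study, assignment)
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(modules):
            for b in modules[i + 1:]:
                r = np.corrcoef(eig.loc[a], eig.loc[b])[0, 1]
                d = 1.0 - r
                if d < dissimilarity_cut and (best is None or d < best[0]):
                    best = (d, a, b)
        if best is None:
            break
        _, a, b = best
        for g, m in assignment.items():
            if m == b:
                assignment[g] = a
        provenance[a] |= provenance.pop(b)

    # relabel deterministically by size
    genes = list(assignment)
    sizes: dict[str, int] = {}
    for m in assignment.values():
        sizes[m] = sizes.get(m, 0) + 1
    mods = sorted(
        (m for m in sizes if m != GREY),
        key=lambda m: (-sizes[m], min(decomposition.genes_of(m), default=m)),
    )
    rename = {m: f"M{i + 1}" for i, m in enumerate(mods)}
    rename[GREY] = GREY
    final_assignment = {g: rename[m] for g, m in assignment.items()}
    eig = module_eigengenes(study, final_assignment)
    merged_from = {
        rename[m]: tuple(sorted(provenance[m])) for m in provenance if m in rename
    }
    return ModuleDecomposition(
        assignment=final_assignment, eigengenes=eig, merged_from=merged_from
    )


def module_trait_correlation(
    decomposition: ModuleDecomposition,
    groups: Mapping[str, str],
    traits: Mapping[str, Mapping[str, int]],
) -> pd.DataFrame:
    """Pearson correlation of each eigengene with each binary trait.

    ``traits`` maps trait name -> {group label: 0 or 1}; samples whose group
    is absent from a trait's encoding are excluded from that trait.  Returns
    a tidy frame (module, trait, r, p, significant) and stores the pairs on
    the decomposition.
    """
    eig = decomposition.eigengenes
    samples = list(eig.columns)
    rows = []
    for trait_name, encoding in traits.items():
        mask = np.array([groups[s] in encoding for s in samples])
        if mask.sum() < 3:
            raise ValueError(f"trait {trait_name!r} covers fewer than 3 samples")
        y = np.array([encoding[groups[s]] for s in samples if groups[s] in encoding],
                     dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError(f"trait {trait_name!r} is constant over its samples")
        n = int(mask.sum())
        for module in eig.index:
            x = eig.loc[module].to_numpy()[mask]
            if np.std(x) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(x, y)
            decomposition.trait_correlation[(module, trait_name)] = (float(r), float(p))
            rows.append(
                {"module": module, "trait": trait_name, "r": r, "p": p,
                 "n": n, "significant": bool(p < 0.05) if np.isfinite(p) else False}
            )
    return pd.DataFrame(rows)
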