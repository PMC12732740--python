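"""Synthetic fixture studies with known truth.

Generates three-group log2 expression matrices with planted differentially
expressed genes, single-latent-factor co-expression modules, probe
multiplicity, plus hub-boosted interaction graphs and gene-set collections —
everything downstream stages need, with ground truth attached.

Seeding: a single global seed is expanded into independent per-component
child streams via ``numpy.random.SeedSequence(seed, spawn_key=(k,))`` with a
fixed component index k, so each stage can be regenerated independently and
identical configs give byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .io import ExpressionStudy, GeneSetCollection

__all__ = ["SimConfig", "SimulatedStudy", "simulate_study", "simulate_graph",
           "simulate_gene_sets"]

# spawn_key component indices
_K_EXPR, _K_GRAPH, _K_SETS = 0, 1, 2

BASELINE_MEAN = 8.0   # log2-intensity grand mean
BASELINE_SD = 1.0     # between-gene spread of baselines


class ConfigError(ValueError):
    """A SimConfig field is invalid; the message names the field."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic expression study.

    ``group_sizes`` maps group label -> sample count; the *last* group in
    insertion order is the designated case group in which DE genes are
    shifted by ``effect_size_log2``.
    """

    n_genes: int = 2000
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: {"Healthy": 5, "Control": 10, "Case": 11}
    )
    n_de_genes: int = 5
    effect_size_log2: float = 2.0
    n_modules: int = 2
    module_size: int = 30
    module_loading: float = 0.8
    noise_sd: float = 0.5
    probes_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_de_genes", "n_modules", "module_size",
                     "probes_per_gene"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < (1 if name in
                    ("n_genes", "probes_per_gene") else 0):
                raise ConfigError(f"{name} must be a non-negative count (got {v!r})")
        if self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes exceeds n_genes")
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigError("n_modules * module_size exceeds n_genes")
        if not 0 <= self.module_loading <= 1:
            raise ConfigError("module_loading must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not self.group_sizes:
            raise ConfigError("group_sizes must be non-empty")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ConfigError(f"group_sizes[{g!r}] must be positive")

    @property
    def case_group(self) -> str:
        return list(self.group_sizes)[-1]


@dataclass(frozen=True)
class SimulatedStudy:
    study: ExpressionStudy
    truth_de_genes: frozenset[str]
    truth_modules: dict[str, frozenset[str]]
    truth_panel: tuple[str, ...]
    config: SimConfig


def _rng(seed: int, component: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(component,)))


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a study per the latent-factor + planted-shift model.

    Module genes follow ``loading * factor + sqrt(1-loading^2) * eps`` (scaled
    by ``noise_sd`` and centred on a per-gene baseline); non-module genes are
    pure gaussian noise around their baseline.  DE genes get a mean shift of
    ``effect_size_log2`` in the case group only.  Probes replicate the gene
    signal with independent residual noise.
    """
    cfg = config
    rng = _rng(cfg.seed, _K_EXPR)
    n_samples = sum(cfg.group_sizes.values())
    labels: list[str] = []
    sample_ids: list[str] = []
    for g, n in cfg.group_sizes.items():
        for i in range(n):
            sample_ids.append(f"{g}_{i + 1:02d}")
            labels.append(g)
    labels_arr = np.array(labels)
    case_mask = (labels_arr == cfg.case_group).astype(float)

    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]

    # module membership: leading block of genes, contiguous
    truth_modules: dict[str, frozenset[str]] = {}
    module_of = np.full(cfg.n_genes, -1, dtype=int)
    for m in range(cfg.n_modules):
        lo, hi = m * cfg.module_size, (m + 1) * cfg.module_size
        module_of[lo:hi] = m
        truth_modules[f"M{m + 1}"] = frozenset(genes[lo:hi])

    # DE genes: taken from the tail so they stay disjoint from modules
    # whenever the budget allows
    de_idx = np.arange(cfg.n_genes - cfg.n_de_genes, cfg.n_genes)
    truth_de = [genes[i] for i in de_idx]

    baselines = BASELINE_MEAN + BASELINE_SD * rng.standard_normal(cfg.n_genes)
    factors = rng.standard_normal((max(cfg.n_modules, 1), n_samples))

    # gene-level signal shared by all probes of a gene
    signal = np.tile(baselines[:, None], (1, n_samples))
    shift = np.zeros(cfg.n_genes)
    shift[de_idx] = cfg.effect_size_log2
    signal += shift[:, None] * case_mask[None, :]
    lam = cfg.module_loading
    in_module = module_of >= 0
    if in_module.any() and lam > 0:
        signal[in_module] += cfg.noise_sd * lam * factors[module_of[in_module]]
    resid_scale = np.where(in_module, np.sqrt(1 - lam**2), 1.0) * cfg.noise_sd

    p = cfg.probes_per_gene
    noise = rng.standard_normal((cfg.n_genes * p, n_samples))
    matrix = np.repeat(signal, p, axis=0) + np.repeat(resid_scale, p)[:, None] * noise

    if p == 1:
        feature_ids = list(genes)
    else:
        feature_ids = [f"{g}_p{k + 1}" for g in genes for k in range(p)]
    feature_to_gene = {f: genes[i // p] for i, f in enumerate(feature_ids)}

    study = ExpressionStudy(
        matrix=matrix,
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        groups=dict(zip(sample_ids, labels)),
        feature_to_gene=feature_to_gene,
    )
    return SimulatedStudy(
        study=study,
        truth_de_genes=frozenset(truth_de),
        truth_modules=truth_modules,
        truth_panel=tuple(truth_de),
        config=cfg,
    )


def simulate_graph(
    genes: Sequence[str],
    planted_hubs: int,
    seed: int = 0,
    m_edges: int = 2,
    hub_boost: float = 50.0,
    hub_degree_factor: float = 3.0,
) -> nx.Graph:
    """Connected preferential-attachment graph with boosted hub nodes.

    The first ``planted_hubs`` genes are the planted hubs: they receive a
    large attachment-weight boost during growth, and afterwards extra edges
    are added until every hub's degree is at least ``hub_degree_factor``
    times the median degree.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("gene list must be non-empty")
    if planted_hubs > len(genes):
        raise ValueError("planted_hubs exceeds number of genes")
    rng = _rng(seed, _K_GRAPH)
    hubs = genes[:planted_hubs]
    g = nx.Graph()
    g.add_nodes_from(genes)
    if len(genes) == 1:
        return g

    order = genes.copy()
    seed_size = min(m_edges + 1, len(genes))
    for i in range(seed_size):
        for j in range(i + 1, seed_size):
            g.add_edge(order[i], order[j])
    hub_set = set(hubs)
    for node in order[seed_size:]:
        existing = [n for n in order if g.degree(n) > 0 and n != node]
        weights = np.array(
            [g.degree(n) * (hub_boost if n in hub_set else 1.0) for n in existing],
            dtype=float,
        )
        weights /= weights.sum()
        k = min(m_edges, len(existing))
        targets = rng.choice(len(existing), size=k, replace=False, p=weights)
        for t in targets:
            g.add_edge(node, existing[t])

    # enforce the hub-degree guarantee
    if hubs:
        for _ in range(10 * len(genes)):
            degrees = np.array([g.degree(n) for n in genes])
            med = float(np.median(degrees))
            needy = [h for h in hubs
                     if g.degree(h) < hub_degree_factor * max(med, 1.0)]
            if not needy:
                break
            for h in needy:
                candidates = [n for n in genes if n != h and not g.has_edge(h, n)]
                if not candidates:
                    break
                g.add_edge(h, candidates[int(rng.integers(len(candidates)))])

    # connect stragglers (possible when m_edges saturates early)
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    anchor = next(iter(sorted(comps[0])))
    for comp in comps[1:]:
        g.add_edge(anchor, next(iter(sorted(comp))))
    return g


def simulate_gene_sets(
    genes: Sequence[str],
    n_sets: int,
    set_size: int,
    n_enriched: int,
    ranked_metric: Sequence[float] | None = None,
    seed: int = 0,
    top_bias: float = 5.0,
) -> GeneSetCollection:
    """Random gene sets, ``n_enriched`` of them biased toward the metric top.

    Enriched sets sample without replacement with weight exp(-top_bias *
    rank / n) over the metric-sorted gene list; the remainder are uniform.
    Set names: ``SET_ENR_i`` for enriched, ``SET_RND_i`` otherwise.
    """
    genes = list(genes)
    if set_size > len(genes):
        raise ValueError("set_size exceeds number of genes")
    if n_enriched > n_sets:
        raise ValueError("n_enriched exceeds n_sets")
    rng = _rng(seed, _K_SETS)
    n = len(genes)
    if ranked_metric is None:
        order = np.arange(n)
    else:
        metric = np.asarray(list(ranked_metric), dtype=float)
        if metric.size != n:
            raise ValueError("ranked_metric length must match genes")
        order = np.argsort(-metric, kind="stable")
    ranked_genes = [genes[i] for i in order]
    weights = np.exp(-top_bias * np.arange(n) / max(n, 1))
    weights /= weights.sum()

    sets: dict[str, frozenset[str]] = {}
    for i in range(n_enriched):
        pick = rng.choice(n, size=set_size, replace=False, p=weights)
        sets[f"SET_ENR_{i + 1}"] = frozenset(ranked_genes[j] for j in pick)
    for i in range(n_sets - n_enriched):
        pick = rng.choice(n, size=set_size, replace=False)
        sets[f"SET_RND_{i + 1}"] = frozenset(ranked_genes[j] for j in pick)
    return GeneSetCollection(sets=sets, universe=frozenset(genes))
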