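"""Hub-gene ranking by eleven graph centralities with consensus intersection.

Local methods: Degree, MNC, DMNC, MCC.  Global methods: EPC (seeded
edge-percolation), BottleNeck, EcCentricity, Closeness (harmonic), Radiality,
Betweenness, Stress.  Disconnected graphs are handled with harmonic /
per-component conventions; unreachable pairs contribute nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["CentralityTable", "ALL_METHODS", "compute_centralities",
           "consensus_hubs"]

ALL_METHODS = (
    "Degree",
    "MNC",
    "DMNC",
    "MCC",
    "EPC",
    "BottleNeck",
    "EcCentricity",
    "Closeness",
    "Radiality",
    "Betweenness",
    "Stress",
)


@dataclass(frozen=True)
class CentralityTable:
    scores: dict[str, dict[str, float]]  # method -> node -> score
    top_k: dict[str, tuple[str, ...]]
    k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores)


def _neighbor_component(g: nx.Graph, v) -> nx.Graph:
    nbrs = list(g.neighbors(v))
    if not nbrs:
        return nx.Graph()
    sub = g.subgraph(nbrs)
    comps = list(nx.connected_components(sub))
    biggest = max(comps, key=lambda c: (len(c), sorted(c)[0]))
    return sub.subgraph(biggest)


def _mnc(g: nx.Graph) -> dict:
    return {v: float(len(_neighbor_component(g, v))) for v in g}


def _dmnc(g: nx.Graph, eps: float = 1.7) -> dict:
    out = {}
    for v in g:
        comp = _neighbor_component(g, v)
        n = comp.number_of_nodes()
        out[v] = float(comp.number_of_edges() / n**eps) if n > 0 else 0.0
    return out


def _mcc(g: nx.Graph) -> dict:
    """Sum over maximal cliques containing v of (|C| - 1)!.

    A node whose only maximal cliques are single edges therefore scores its
    degree; an isolated node scores 0.
    """
    out = {v: 0.0 for v in g}
    for clique in nx.find_cliques(g):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += w
    return out


def _epc(g: nx.Graph, r: int, p_keep: float, seed: int) -> dict:
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes())
    edges = sorted(tuple(sorted(e)) for e in g.edges())
    totals = {v: 0.0 for v in nodes}
    for _ in range(r):
        keep = rng.random(len(edges)) < p_keep
        h = nx.Graph()
        h.add_nodes_from(nodes)
        h.add_edges_from(e for e, k in zip(edges, keep) if k)
        for comp in nx.connected_components(h):
            size = float(len(comp))
            for v in comp:
                totals[v] += size
    return {v: totals[v] / r for v in nodes}


def _bottleneck(g: nx.Graph, fraction: float = 0.25) -> dict:
    """For each source's shortest-path tree, flag nodes that more than
    ``fraction * n_tree`` of the tree's root-to-node paths pass through."""
    out = {v: 0.0 for v in g}
    for s in sorted(g.nodes()):
        preds, _ = nx.dijkstra_predecessor_and_distance(g, s)
        # tree with the first predecessor (deterministic by sorted order)
        children: dict = {v: [] for v in preds}
        for v, plist in preds.items():
            if plist:
                children[sorted(plist)[0]].append(v)
        # subtree sizes by post-order
        size: dict = {}
        stack = [(s, False)]
        while stack:
            node, done = stack.pop()
            if done:
                size[node] = 1 + sum(size[c] for c in children.get(node, []))
            else:
                stack.append((node, True))
                for c in children.get(node, []):
                    stack.append((c, False))
        n_tree = size.get(s, 1)
        for v in size:
            if size[v] > fraction * n_tree:
                out[v] += 1.0
    return out


def _distance_scores(g: nx.Graph) -> tuple[dict, dict, dict]:
    """(EcCentricity, harmonic Closeness, Radiality) in one sweep."""
    ecc, clo, rad = {}, {}, {}
    # per-component diameter for radiality
    comp_of = {}
    diam = {}
    for ci, comp in enumerate(nx.connected_components(g)):
        sub = g.subgraph(comp)
        d = nx.diameter(sub) if len(comp) > 1 else 0
        for v in comp:
            comp_of[v] = ci
        diam[ci] = d
    n = g.number_of_nodes()
    for v in g:
        dists = nx.single_source_shortest_path_length(g, v)
        others = {u: d for u, d in dists.items() if u != v}
        ecc[v] = 1.0 / max(others.values()) if others else 0.0
        clo[v] = sum(1.0 / d for d in others.values())
        dmax = diam[comp_of[v]]
        rad[v] = (
            sum(dmax + 1 - d for d in others.values()) / (n - 1) if n > 1 else 0.0
        )
    return ecc, clo, rad


def _stress(g: nx.Graph) -> dict:
    """Number of shortest paths with each node strictly interior.

    Uses the path-counting identity sigma_st(v) = sigma_sv * sigma_vt when
    d(s,v) + d(v,t) = d(s,t); each unordered pair {s,t} counts once.
    """
    nodes = sorted(g.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    sigma = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        dist[si, si] = 0.0
        sigma[si, si] = 1.0
        queue = [s]
        while queue:
            v = queue.pop(0)
            vi = idx[v]
            for w in g.neighbors(v):
                wi = idx[w]
                if not np.isfinite(dist[si, wi]):
                    dist[si, wi] = dist[si, vi] + 1
                    queue.append(w)
                if dist[si, wi] == dist[si, vi] + 1:
                    sigma[si, wi] += sigma[si, vi]
    out = {}
    for v in nodes:
        vi = idx[v]
        # mask of pairs (s,t) whose shortest paths can pass through v
        through = dist[:, vi][:, None] + dist[vi, :][None, :] == dist
        counts = sigma[:, vi][:, None] * sigma[vi, :][None, :]
        counts = np.where(through & np.isfinite(dist), counts, 0.0)
        counts[vi, :] = 0.0
        counts[:, vi] = 0.0
        np.fill_diagonal(counts, 0.0)
        out[v] = float(counts.sum() / 2.0)
    return out


def compute_centralities(
    graph: nx.Graph,
    methods: Sequence[str] = ALL_METHODS,
    k: int = 10,
    epc_rounds: int = 1000,
    epc_p_keep: float = 0.5,
    seed: int = 0,
) -> CentralityTable:
    """Score every node under the requested centrality methods.

    Top-k lists break score ties by node id so results are deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    unknown = [m for m in methods if m not in ALL_METHODS]
    if unknown:
        raise ValueError(
            f"unknown methods {unknown}; valid methods: {list(ALL_METHODS)}"
        )
    g = graph
    scores: dict[str, dict[str, float]] = {}
    need_dist = {"EcCentricity", "Closeness", "Radiality"} & set(methods)
    ecc = clo = rad = None
    if need_dist:
        ecc, clo, rad = _distance_scores(g)
    for m in methods:
        if m == "Degree":
            scores[m] = {v: float(d) for v, d in g.degree()}
        elif m == "MNC":
            scores[m] = _mnc(g)
        elif m == "DMNC":
            scores[m] = _dmnc(g)
        elif m == "MCC":
            scores[m] = _mcc(g)
        elif m == "EPC":
            scores[m] = _epc(g, epc_rounds, epc_p_keep, seed)
        elif m == "BottleNeck":
            scores[m] = _bottleneck(g)
        elif m == "EcCentricity":
            scores[m] = dict(ecc)
        elif m == "Closeness":
            scores[m] = dict(clo)
        elif m == "Radiality":
            scores[m] = dict(rad)
        elif m == "Betweenness":
            scores[m] = {v: float(b) for v, b in
                         nx.betweenness_centrality(g, normalized=False).items()}
        elif m == "Stress":
            scores[m] = _stress(g)
    top_k = {
        m: tuple(sorted(sc, key=lambda v: (-sc[v], v))[:k])
        for m, sc in scores.items()
    }
    return CentralityTable(scores=scores, top_k=top_k, k=k)


def consensus_hubs(
    table: CentralityTable, m_threshold: int = 3
) -> tuple[set[str], pd.DataFrame]:
    """Nodes appearing in the top-k of at least ``m_threshold`` methods.

    Also returns an UpSet-style per-node method-count table sorted by count
    descending (ties by node id).
    """
    if m_threshold > len(table.top_k):
        raise ValueError("m_threshold exceeds the number of computed methods")
    counts: dict[str, int] = {}
    membership: dict[str, list[str]] = {}
    for method, nodes in table.top_k.items():
        for v in nodes:
            counts[v] = counts.get(v, 0) + 1
            membership.setdefault(v, []).append(method)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    frame = pd.DataFrame(
        {
            "node": [v for v, _ in rows],
            "n_methods": [c for _, c in rows],
            "methods": [",".join(sorted(membership[v])) for v, _ in rows],
        }
    )
    hubs = {v for v, c in counts.items() if c >= m_threshold}
    return hubs, frame
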