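"""Expression-matrix, phenotype, gene-set and graph I/O plus matrix preprocessing.

All expression matrices are oriented features x samples and assumed to be on
the log2 scale.  Readers tolerate CRLF line endings and ``#`` comment lines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionStudy",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "quantile_normalize",
    "collapse_to_genes",
    "variance_filter",
]


class ParseError(ValueError):
    """Raised when an input file violates the expected layout."""


@dataclass(frozen=True)
class ExpressionStudy:
    """A log2 expression matrix with sample group labels.

    Parameters
    ----------
    matrix : (n_features, n_samples) float array
    feature_ids : feature identifiers, unique, one per matrix row
    sample_ids : sample identifiers, unique, one per matrix column
    groups : mapping sample id -> group label, covering every sample
    feature_to_gene : optional mapping feature id -> gene symbol, used by
        :func:`collapse_to_genes`
    """

    matrix: np.ndarray
    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    groups: dict[str, str]
    feature_to_gene: dict[str, str] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "feature_ids", tuple(self.feature_ids))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        if m.ndim != 2:
            raise ParseError("expression matrix must be 2-dimensional")
        if m.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ParseError(
                f"matrix shape {m.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ParseError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ParseError("duplicate sample ids")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ParseError(f"samples missing group labels: {missing}")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def group_labels(self) -> np.ndarray:
        return np.array([self.groups[s] for s in self.sample_ids])

    def samples_in(self, group: str) -> np.ndarray:
        """Column indices of samples with the given group label."""
        labels = self.group_labels()
        idx = np.flatnonzero(labels == group)
        if idx.size == 0:
            raise KeyError(f"no samples in group {group!r}")
        return idx

    def values(self, feature: str) -> np.ndarray:
        try:
            i = self.feature_ids.index(feature)
        except ValueError:
            raise KeyError(f"unknown feature {feature!r}") from None
        return self.matrix[i]

    def subset_features(self, features: Iterable[str]) -> "ExpressionStudy":
        keep = list(features)
        index = {f: i for i, f in enumerate(self.feature_ids)}
        unknown = [f for f in keep if f not in index]
        if unknown:
            raise KeyError(f"unknown features: {unknown}")
        rows = [index[f] for f in keep]
        f2g = None
        if self.feature_to_gene is not None:
            f2g = {f: self.feature_to_gene[f] for f in keep if f in self.feature_to_gene}
        return ExpressionStudy(
            matrix=self.matrix[rows],
            feature_ids=keep,
            sample_ids=self.sample_ids,
            groups=dict(self.groups),
            feature_to_gene=f2g,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.feature_ids), columns=list(self.sample_ids)
        )


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets restricted to a common gene universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sets", {k: frozenset(v) for k, v in self.sets.items()}
        )
        object.__setattr__(self, "universe", frozenset(self.universe))
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def restricted_to(self, universe: Iterable[str]) -> "GeneSetCollection":
        uni = frozenset(universe)
        sets = {}
        for name, members in self.sets.items():
            kept = members & uni
            if kept:
                sets[name] = kept
        return GeneSetCollection(sets=sets, universe=uni)


def _data_lines(path: Path) -> list[str]:
    lines = []
    with open(path, "r", newline="") as fh:
        for raw in fh:
            line = raw.rstrip("\r\n")
            if not line or line.startswith("#"):
                continue
            lines.append(line)
    return lines


def _sniff_sep(path: Path) -> str:
    return "," if Path(path).suffix.lower() == ".csv" else "\t"


def read_expression(path: str | Path, phenotype_path: str | Path) -> ExpressionStudy:
    """Read an expression matrix and phenotype table into an ExpressionStudy.

    The expression file has a header row of sample ids and a first column of
    feature ids.  The phenotype file has two columns (sample_id, group), with
    or without a header; samples are returned in phenotype-file order.
    Samples present in the matrix but absent from the phenotype table are an
    error, as are dimension mismatches, duplicates and non-numeric cells.
    """
    path, phenotype_path = Path(path), Path(phenotype_path)
    lines = _data_lines(path)
    if not lines:
        raise ParseError(f"{path}: empty expression file")
    sep = _sniff_sep(path)
    header = lines[0].split(sep)
    sample_ids = [c.strip() for c in header[1:]]
    if not sample_ids:
        raise ParseError(f"{path}: header row has no sample columns")
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split(sep)
        if len(cells) != len(sample_ids) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                f"found {len(cells)}"
            )
        feature_ids.append(cells[0].strip())
        try:
            rows.append([float(c) for c in cells[1:]])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None

    groups: dict[str, str] = {}
    order: list[str] = []
    plines = _data_lines(phenotype_path)
    psep = _sniff_sep(phenotype_path)
    for lineno, line in enumerate(plines, start=1):
        cells = [c.strip() for c in line.split(psep)]
        if len(cells) < 2:
            raise ParseError(f"{phenotype_path}:{lineno}: expected 2 columns")
        sid, grp = cells[0], cells[1]
        if lineno == 1 and sid.lower() in {"sample", "sample_id", "id"}:
            continue
        if sid in groups:
            raise ParseError(f"{phenotype_path}:{lineno}: duplicate sample {sid!r}")
        groups[sid] = grp
        order.append(sid)

    missing = [s for s in sample_ids if s not in groups]
    if missing:
        raise ParseError(
            f"{phenotype_path}: samples missing from phenotype table: {missing}"
        )
    # order samples as in the phenotype file, dropping phenotype-only entries
    present = set(sample_ids)
    ordered = [s for s in order if s in present]
    col = {s: j for j, s in enumerate(sample_ids)}
    matrix = np.array(rows, dtype=float)[:, [col[s] for s in ordered]]
    return ExpressionStudy(
        matrix=matrix,
        feature_ids=feature_ids,
        sample_ids=ordered,
        groups={s: groups[s] for s in ordered},
    )


def write_expression(
    study: ExpressionStudy, path: str | Path, phenotype_path: str | Path | None = None
) -> None:
    path = Path(path)
    sep = _sniff_sep(path)
    with open(path, "w") as fh:
        fh.write(sep.join(["feature_id", *study.sample_ids]) + "\n")
        for i, fid in enumerate(study.feature_ids):
            vals = sep.join(repr(float(v)) for v in study.matrix[i])
            fh.write(f"{fid}{sep}{vals}\n")
    if phenotype_path is not None:
        with open(phenotype_path, "w") as fh:
            fh.write("sample_id\tgroup\n")
            for s in study.sample_ids:
                fh.write(f"{s}\t{study.groups[s]}\n")


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name <tab> description <tab> members..."""
    sets: dict[str, frozenset[str]] = {}
    members_all: set[str] = set()
    for lineno, line in enumerate(_data_lines(Path(path)), start=1):
        cells = line.split("\t")
        if len(cells) < 3:
            raise ParseError(f"{path}:{lineno}: GMT rows need name, description, members")
        name = cells[0]
        members = frozenset(c for c in cells[2:] if c)
        if name in sets:
            raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = members
        members_all |= members
    uni = frozenset(universe) if universe is not None else frozenset(members_all)
    return GeneSetCollection(sets=sets, universe=uni).restricted_to(uni)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = sorted(collection.sets[name])
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected two-column edge-list TSV into a networkx graph."""
    g = nx.Graph()
    for lineno, line in enumerate(_data_lines(Path(path)), start=1):
        cells = [c.strip() for c in line.split("\t")]
        if len(cells) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns")
        a, b = cells[0], cells[1]
        if lineno == 1 and {a.lower(), b.lower()} & {"gene_a", "source", "node1"}:
            continue
        if a == b:
            continue  # self-loops dropped
        g.add_edge(a, b)
    return g


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def quantile_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Force every sample to share the mean empirical distribution.

    After normalization each column's sorted values equal the across-sample
    mean of sorted values.  Ties within a column receive the mean of the
    reference quantiles they span (average-rank convention).
    """
    if study.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = study.matrix
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.take_along_axis(x, order, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        # average rank over ties -> mean of spanned reference quantiles
        sorter = order[:, j]
        ranks = np.empty(len(col), dtype=float)
        ranks[sorter] = np.arange(len(col), dtype=float)
        vals = col[sorter]
        # group equal values and average their reference entries
        normalized = np.empty(len(col), dtype=float)
        i = 0
        while i < len(vals):
            k = i
            while k + 1 < len(vals) and vals[k + 1] == vals[i]:
                k += 1
            normalized[i : k + 1] = ref[i : k + 1].mean()
            i = k + 1
        out[sorter, j] = normalized
    return replace(study, matrix=out)


def collapse_to_genes(study: ExpressionStudy, method: str = "max_mean") -> ExpressionStudy:
    """Collapse probe-level rows to one row per gene symbol.

    ``max_mean`` keeps, per gene, the probe with the highest mean expression;
    ``mean`` averages all probes of a gene elementwise.  Requires
    ``feature_to_gene``; any unmapped feature is an error.
    """
    if study.feature_to_gene is None:
        raise ValueError("collapse_to_genes requires a feature_to_gene mapping")
    if method not in {"max_mean", "mean"}:
        raise ValueError(f"unknown collapse method {method!r}")
    unmapped = [f for f in study.feature_ids if f not in study.feature_to_gene]
    if unmapped:
        raise ValueError(f"features without gene mapping: {unmapped[:5]}")
    by_gene: dict[str, list[int]] = {}
    gene_order: list[str] = []
    for i, f in enumerate(study.feature_ids):
        g = study.feature_to_gene[f]
        if g not in by_gene:
            by_gene[g] = []
            gene_order.append(g)
        by_gene[g].append(i)
    rows = []
    for g in gene_order:
        idx = by_gene[g]
        sub = study.matrix[idx]
        if method == "mean" and len(idx) > 1:
            rows.append(sub.mean(axis=0))
        else:
            rows.append(sub[int(np.argmax(sub.mean(axis=1)))])
    return ExpressionStudy(
        matrix=np.array(rows),
        feature_ids=gene_order,
        sample_ids=study.sample_ids,
        groups=dict(study.groups),
        feature_to_gene={g: g for g in gene_order},
    )


def variance_filter(study: ExpressionStudy, keep_fraction: float) -> ExpressionStudy:
    """Keep the ceil(keep_fraction * n) most variable features.

    Sample variance (n-1 denominator); ties broken by feature id so the
    result is deterministic.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    n_keep = math.ceil(keep_fraction * study.n_features)
    variances = study.matrix.var(axis=1, ddof=1)
    ranked = sorted(
        range(study.n_features), key=lambda i: (-variances[i], study.feature_ids[i])
    )
    keep = sorted(ranked[:n_keep])  # preserve original row order
    return study.subset_features([study.feature_ids[i] for i in keep])
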