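"""Orchestration of the discovery and validation workflows.

Discovery: differential expression -> co-expression modules -> intersection
of screen hits with trait-significant module genes -> sparse panel selection
(L1 path) and network hub ranking on the candidate pool.  Validation: nested
CV with Firth models plus the safe stratified 0.632+ bootstrap.  Every run
writes tidy TSV artifacts and a JSON manifest with per-stage hashes and
timings.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from . import coexpr, dex, netrank, select, validate
from .io import ExpressionStudy

log = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "lfc_cut": 1.0,
    "p_cut": 0.05,
    "min_module_size": 20,
    "merge_cut": 0.25,
    "cut_height": 0.95,
    "folds": 10,
    "outer_folds": 5,
    "top_m": 5,
    "B": 200,
    "P": 200,
    "auc_gate": 0.9,
    "padj_gate": 0.003,
    "min_methods": 3,
    "top_k": 10,
    "seed": 0,
}


@dataclass
class RunManifest:
    config: dict[str, Any]
    stages: list[dict[str, Any]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record(self, stage: str, seconds: float, outputs: Mapping[str, Path]) -> None:
        self.stages.append(
            {
                "stage": stage,
                "seconds": round(seconds, 3),
                "outputs": {k: str(p) for k, p in outputs.items()},
                "sha256": {k: _file_hash(p) for k, p in outputs.items()},
            }
        )

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"config": self.config, "stages": self.stages,
             "warnings": self.warnings}, indent=2))


def _file_hash(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index)


def run_discovery(
    study: ExpressionStudy,
    group_pos: str,
    group_neg: str,
    out_dir: str | Path,
    graph: nx.Graph | None = None,
    params: Mapping[str, Any] | None = None,
) -> RunManifest:
    """Discovery workflow for one two-group comparison.

    ``group_pos`` is the case group.  Returns the manifest; artifacts land
    in ``out_dir``: dex table, module assignment/eigengenes/trait tables,
    candidate pool, regularization path and panels, centrality scores and
    consensus hubs.
    """
    cfg = {**DEFAULTS, **(params or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config={**cfg, "comparison": [group_pos, group_neg]}
    )

    t0 = time.perf_counter()
    records = dex.moderated_t(study, group_pos, group_neg)
    degs = dex.screen_degs(records, cfg["lfc_cut"], cfg["p_cut"])
    dex_path = out / "dex.tsv"
    _write_tsv(dex.records_to_frame(records), dex_path)
    manifest.record("dex", time.perf_counter() - t0, {"dex": dex_path})
    log.info("screen: %d genes pass |log2FC|>%g and p<%g",
             len(degs), cfg["lfc_cut"], cfg["p_cut"])
    if not degs:
        manifest.warnings.append(
            "empty screen-hit set: downstream discovery stages skipped")
        manifest.write(out / "manifest.json")
        return manifest

    t0 = time.perf_counter()
    scan = coexpr.scan_soft_threshold(study)
    log.info("soft threshold: power=%d (target reached: %s)",
             scan.chosen_power, scan.reached_target)
    decomp = coexpr.detect_modules(
        study, scan.chosen_power, cfg["min_module_size"], cfg["cut_height"]
    )
    decomp = coexpr.merge_modules(study, decomp, cfg["merge_cut"])
    traits = {f"{group_pos}_vs_{group_neg}": {group_pos: 1, group_neg: 0}}
    trait_table = coexpr.module_trait_correlation(decomp, study.groups, traits)
    assign_path = out / "modules.tsv"
    _write_tsv(
        pd.DataFrame(
            {"gene": list(decomp.assignment),
             "module": list(decomp.assignment.values())}
        ),
        assign_path,
    )
    eig_path = out / "eigengenes.tsv"
    decomp.eigengenes.to_csv(eig_path, sep="\t", index_label="module")
    trait_path = out / "module_trait.tsv"
    _write_tsv(trait_table, trait_path)
    manifest.record("coexpr", time.perf_counter() - t0,
                    {"modules": assign_path, "eigengenes": eig_path,
                     "module_trait": trait_path})

    significant_modules = set(
        trait_table.loc[trait_table["significant"], "module"]
    )
    module_genes: set[str] = set()
    for m in significant_modules:
        module_genes.update(decomp.genes_of(m))
    pool = sorted(degs & module_genes) if module_genes else sorted(degs)
    if not module_genes:
        manifest.warnings.append(
            "no trait-significant module: candidate pool falls back to screen hits")
    log.info("candidate pool: %d genes (screen hits ∩ significant-module genes)",
             len(pool))
    pool_path = out / "candidate_pool.tsv"
    _write_tsv(pd.DataFrame({"gene": pool}), pool_path)
    manifest.record("intersection", 0.0, {"pool": pool_path})
    if not pool:
        manifest.warnings.append("empty candidate pool: selection stages skipped")
        manifest.write(out / "manifest.json")
        return manifest

    t0 = time.perf_counter()
    path = select.lasso_cv(
        study.subset_features(pool), group_pos, group_neg,
        n_folds=cfg["folds"], seed=cfg["seed"],
    )
    log.info("lasso: lambda_min=%.4g (%d genes), lambda_1se=%.4g (%d genes)",
             path.lambda_min, len(path.panel_min),
             path.lambda_1se, len(path.panel_1se))
    path_tsv = out / "lasso_path.tsv"
    _write_tsv(path.to_frame(), path_tsv)
    panel_tsv = out / "panels.tsv"
    _write_tsv(
        pd.DataFrame(
            {"rule": ["min"] * len(path.panel_min) + ["1se"] * len(path.panel_1se),
             "gene": list(path.panel_min) + list(path.panel_1se)}
        ),
        panel_tsv,
    )
    manifest.record("select", time.perf_counter() - t0,
                    {"path": path_tsv, "panels": panel_tsv})

    if graph is not None:
        t0 = time.perf_counter()
        nodes = [n for n in graph.nodes() if n in set(pool)]
        sub = graph.subgraph(nodes).copy()
        if sub.number_of_nodes() >= 2:
            table = netrank.compute_centralities(
                sub, k=cfg["top_k"], seed=cfg["seed"])
            hubs, counts = netrank.consensus_hubs(table, cfg["min_methods"])
            scores_path = out / "centrality_scores.tsv"
            table.to_frame().to_csv(scores_path, sep="\t", index_label="node")
            hubs_path = out / "consensus_hubs.tsv"
            _write_tsv(counts, hubs_path)
            manifest.record("netrank", time.perf_counter() - t0,
                            {"scores": scores_path, "hubs": hubs_path})
            log.info("consensus hubs (>=%d methods): %d nodes",
                     cfg["min_methods"], len(hubs))
        else:
            manifest.warnings.append(
                "interaction graph shares <2 nodes with the candidate pool")

    manifest.write(out / "manifest.json")
    return manifest


def run_validation(
    study: ExpressionStudy,
    panel: Sequence[str],
    group_pos: str,
    group_neg: str,
    out_dir: str | Path,
    params: Mapping[str, Any] | None = None,
) -> tuple[RunManifest, validate.ValidationReport, validate.NestedCvResult]:
    """Validation workflow: nested CV + 0.632+ bootstrap on a fixed panel."""
    cfg = {**DEFAULTS, **(params or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = [g for g in panel if g in study.feature_ids]
    if not panel:
        raise ValueError("panel is empty after intersecting with features")
    manifest = RunManifest(
        config={**cfg, "comparison": [group_pos, group_neg], "panel": panel}
    )

    t0 = time.perf_counter()
    nested = validate.nested_cv_firth(
        study, panel, group_pos, group_neg,
        outer_folds=cfg["outer_folds"], top_m=min(cfg["top_m"], len(panel)),
        seed=cfg["seed"],
    )
    t_nested = time.perf_counter() - t0
    t0 = time.perf_counter()
    report = validate.boot632_validate(
        study, panel, group_pos, group_neg,
        B=cfg["B"], P=cfg["P"], seed=cfg["seed"],
    )
    t_boot = time.perf_counter() - t0

    payload = {
        "nested_cv": {
            "auc": nested.roc.auc,
            "selected_genes_per_fold": [list(s) for s in
                                        nested.selected_genes_per_fold],
            "oof_scores": nested.oof_scores.tolist(),
            "labels": nested.labels.tolist(),
        },
        "boot632": {
            "oob_mean": report.boot.oob_mean,
            "oob_median": report.boot.oob_median,
            "ci95": list(report.boot.ci95),
            "mean_632plus": report.boot.mean_632plus,
            "n_accepted": report.boot.n_accepted,
            "empirical_p": report.empirical_p,
            "cohens_d": report.cohens_d,
            "perm_aucs": report.perm_aucs.tolist(),
            "iterations": [
                {"apparent_auc": it.apparent_auc, "oob_auc": it.oob_auc,
                 "auc_632plus": it.auc_632plus,
                 "n_components": it.n_components, "accepted": it.accepted}
                for it in report.boot.iterations
            ],
        },
        "config": manifest.config,
    }
    report_path = out / "validation.json"
    report_path.write_text(json.dumps(payload, indent=2))
    summary_path = out / "validation_summary.tsv"
    _write_tsv(
        pd.DataFrame(
            [{"nested_cv_auc": nested.roc.auc,
              "oob_mean_auc": report.boot.oob_mean,
              "oob_median_auc": report.boot.oob_median,
              "mean_632plus_auc": report.boot.mean_632plus,
              "ci95_lo": report.boot.ci95[0], "ci95_hi": report.boot.ci95[1],
              "empirical_p": report.empirical_p,
              "cohens_d": report.cohens_d}]
        ),
        summary_path,
    )
    manifest.record("nested_cv", t_nested, {})
    manifest.record("boot632", t_boot,
                    {"report": report_path, "summary": summary_path})
    manifest.write(out / "manifest.json")
    return manifest, report, nested
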