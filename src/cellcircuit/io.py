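"""Readers, writers and the end-to-end pipeline orchestration.

All tables are UTF-8 TSV with header rows; expression matrices can also be
stored as MatrixMarket MTX with ``.rows.txt``/``.cols.txt`` sidecars.  A
pipeline run writes a JSON manifest recording parameters and seeds so that
identical configuration reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .differential import differential_circuits
from .hallmarks import annotate_circuits, gene_hallmarks, hallmark_summary, read_gmt
from .pathways import PathwayGraph, extract_circuits, load_pathways
from .perturb import load_drug_table, simulate_drug
from .preprocess import (
    ClusterLabels,
    GeneExpressionMatrix,
    adjusted_rand,
    cluster_cells,
    impute_dropouts,
    normalize_expression,
    rand_index,
)
from .propagation import CircuitActivityMatrix, PropagationSettings, activity_matrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- expression


def _validate_gene_table(df: pd.DataFrame, path) -> None:
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique()[0]
        raise ValueError(f"{path}: duplicate gene symbol {dup!r}")


def read_expression(
    path: str | Path, fmt: str | None = None, stage: str = "counts"
) -> GeneExpressionMatrix:
    """Read a genes x cells matrix from TSV or MTX (+ name sidecars)."""
    path = Path(path)
    if fmt is None:
        fmt = "mtx" if path.suffix == ".mtx" else "tsv"
    if fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            raise ValueError(f"{path}: non-numeric entries in column {bad[0]!r}")
        df = df.astype(float)
    elif fmt == "mtx":
        mat = spio.mmread(path)
        genes = Path(str(path) + ".rows.txt").read_text(encoding="utf-8").split()
        cells = Path(str(path) + ".cols.txt").read_text(encoding="utf-8").split()
        df = pd.DataFrame(np.asarray(mat.todense(), dtype=float), index=genes, columns=cells)
    else:
        raise ValueError(f"unknown expression format {fmt!r}")
    _validate_gene_table(df, path)
    return GeneExpressionMatrix(values=df, stage=stage)


def write_expression(m: GeneExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene")


def write_expression_mtx(m: GeneExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    spio.mmwrite(str(path), sparse.csr_matrix(m.values.to_numpy()))
    Path(str(path) + ".rows.txt").write_text("\n".join(m.genes) + "\n", encoding="utf-8")
    Path(str(path) + ".cols.txt").write_text("\n".join(m.cells) + "\n", encoding="utf-8")


# ------------------------------------------------------------------ activity


def write_activity(acts: CircuitActivityMatrix, path: str | Path) -> None:
    acts.values.to_csv(path, sep="\t", index_label="circuit_id")
    sidecar = Path(str(path) + ".settings.json")
    sidecar.write_text(
        json.dumps({"settings": acts.settings, "diagnostics": acts.diagnostics}, indent=1),
        encoding="utf-8",
    )


def read_activity(path: str | Path) -> CircuitActivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    sidecar = Path(str(path) + ".settings.json")
    meta = json.loads(sidecar.read_text(encoding="utf-8")) if sidecar.exists() else {}
    return CircuitActivityMatrix(
        values=df,
        settings=meta.get("settings", {}),
        diagnostics=meta.get("diagnostics", {}),
    )


# -------------------------------------------------------------------- labels


def write_labels(labels: ClusterLabels, path: str | Path) -> None:
    df = pd.DataFrame({"cell": labels.labels.index, "cluster": labels.labels.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: label files need two columns (cell, label)")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="cluster")


def write_pathways(
    graphs: list[PathwayGraph], edge_path: str | Path, node_path: str | Path
) -> None:
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tsource\tsign\ttarget\n")
        for g in graphs:
            for src, tgt, sign in g.edges:
                fh.write(f"{g.pathway_id}\t{src}\t{sign}\t{tgt}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("pathway_id\tnode_id\tgenes\tlabel\n")
        for g in graphs:
            for nid, spec in g.nodes.items():
                fh.write(f"{g.pathway_id}\t{nid}\t{','.join(spec.genes)}\t{spec.label}\n")


# ------------------------------------------------------------------ pipeline


@dataclass
class PipelineConfig:
    """Paths, toggles and parameters of a full run."""

    expression: str
    pathway_edges: str
    pathway_nodes: str
    outdir: str
    hallmark_gmt: str | None = None
    drug_table: str | None = None
    reference_labels: str | None = None
    contrast_labels: str | None = None  # two-group labels for differential stage

    impute: bool = True
    perturb: bool = False
    k_clusters: int = 3
    k_grid: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    quantile: float = 0.99
    rule: str = "mean"
    missing_default: float = 0.5
    tol: float = 1e-6
    max_iter: int = 100
    alpha: float = 0.05
    eps: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        for name in ("expression", "pathway_edges", "pathway_nodes"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("hallmark_gmt", "drug_table", "reference_labels", "contrast_labels"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.perturb and self.drug_table is None:
            raise ValueError("perturb stage enabled but no drug table configured")


def run_pipeline(cfg: PipelineConfig) -> Path:
    """impute -> normalize -> activities -> cluster -> differential -> hallmarks -> perturb.

    Each stage's outputs are written under ``cfg.outdir``; any failure is
    re-raised with the stage name attached.  Returns the output directory.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "cellcircuit",
        "version": __version__,
        "config": asdict(cfg),
        "stages": [],
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        expr = read_expression(cfg.expression)
        graphs = load_pathways(cfg.pathway_edges, cfg.pathway_nodes)
        circuits = []
        for g in graphs:
            circuits.extend(extract_circuits(g))
        logger.info("loaded %d genes x %d cells, %d pathways, %d circuits",
                    expr.n_genes, expr.n_cells, len(graphs), len(circuits))

        if cfg.impute:
            stage("impute")
            expr = impute_dropouts(expr, k_grid=cfg.k_grid, seed=cfg.seed)
            write_expression(expr, outdir / "imputed.tsv")

        stage("normalize")
        norm = normalize_expression(expr, q=cfg.quantile)
        write_expression(norm, outdir / "normalized.tsv")

        stage("activity")
        settings = PropagationSettings(
            rule=cfg.rule, missing_default=cfg.missing_default,
            tol=cfg.tol, max_iter=cfg.max_iter,
        )
        acts = activity_matrix(norm, circuits, graphs, settings)
        write_activity(acts, outdir / "activity.tsv")

        stage("cluster")
        labels = cluster_cells(acts, k=cfg.k_clusters, seed=cfg.seed)
        write_labels(labels, outdir / "clusters.tsv")
        if cfg.reference_labels:
            ref = read_labels(cfg.reference_labels)
            agreement = {
                "rand_index": rand_index(labels, ref),
                "adjusted_rand": adjusted_rand(labels, ref),
            }
            (outdir / "cluster_agreement.json").write_text(
                json.dumps(agreement, indent=1), encoding="utf-8"
            )
            manifest["cluster_agreement"] = agreement

        circuit_ann = None
        if cfg.hallmark_gmt:
            node_genes = {g.pathway_id: g.node_genes() for g in graphs}
            ann = gene_hallmarks(read_gmt(cfg.hallmark_gmt))
            circuit_ann = annotate_circuits(circuits, ann, node_genes)

        if cfg.contrast_labels:
            stage("differential")
            contrast = read_labels(cfg.contrast_labels)
            table = differential_circuits(acts, contrast, alpha=cfg.alpha)
            table.to_csv(outdir / "differential.tsv", sep="\t", index=False)
            if circuit_ann is not None:
                stage("hallmarks")
                summary = hallmark_summary({"contrast": table}, circuit_ann)
                summary.counts.to_csv(outdir / "hallmark_counts.tsv", sep="\t")
                (outdir / "hallmark_summary.json").write_text(
                    json.dumps(
                        {
                            "meta": summary.meta,
                            "pct_of_significant": summary.pct_of_significant.to_dict(),
                            "pct_of_annotated": summary.pct_of_annotated.to_dict(),
                        },
                        indent=1,
                    ),
                    encoding="utf-8",
                )

        if cfg.perturb:
            stage("perturb")
            drugs = load_drug_table(cfg.drug_table)
            for drug in drugs:
                res = simulate_drug(
                    norm, drug, circuits, graphs, settings,
                    baseline=acts, eps=cfg.eps, seed=cfg.seed,
                )
                prefix = outdir / f"perturbation_{drug.name}"
                res.lfc.to_csv(f"{prefix}.lfc.tsv", sep="\t", index_label="circuit_id")
                per_cell = pd.DataFrame({"impact": res.impact})
                if res.labels is not None:
                    per_cell["response"] = res.labels
                per_cell.to_csv(f"{prefix}.cells.tsv", sep="\t", index_label="cell")
                if res.skipped_targets:
                    logger.warning("drug %s: skipped targets %s", drug.name, res.skipped_targets)

    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        manifest["failed_stage"] = failed
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
        raise RuntimeError(f"pipeline failed in stage {failed!r}: {exc}") from exc

    manifest["status"] = "complete"
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return outdir
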