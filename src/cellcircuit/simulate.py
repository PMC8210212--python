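"""Synthetic single-cell data with full ground truth.

The generator emulates the features the pipeline must cope with: clustered
cell populations with negative-binomial counts and cell-specific library
sizes, expression-dependent dropout (low-expression transcripts vanish far
more often than abundant ones), signed pathway graphs with multi-gene
nodes, circuits whose member genes are shifted in designated cell types
(planted differential activity), and a planted drug-resistant
subpopulation: a fraction of one cell type expresses the drug target at a
tenth of its usual level while a compensator ligand sitting in the *same*
receptor node is boosted five-fold, so the node — and the circuits fed by
it — stays active and insensitive to target knockdown.

Everything is deterministic given the seed, and the pre-dropout matrix is
kept so imputation accuracy can be scored against truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .hallmarks import CANONICAL_HALLMARKS
from .pathways import ACTIVATION, INHIBITION, Circuit, NodeSpec, PathwayGraph, extract_circuits
from .preprocess import GeneExpressionMatrix


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Pathway topology: ``n_pathways`` random DAGs of ``nodes_per_pathway``
    nodes, edge probability ``edge_density`` between ordered node pairs,
    each edge inhibitory with probability ``p_inhibition``, and
    ``genes_per_node`` genes drawn per node.  Pathway 0 is the "drug
    pathway": one of its receptor nodes carries both the drug target and
    the compensator ligand.

    Cells: ``n_cell_types`` types of ``cells_per_type`` cells.  Gene base
    means are log-normal (median ~e^``base_mean_log``).  Each type is
    assigned one non-drug pathway round-robin; the genes of that pathway's
    circuits are shifted by ``delta_log2`` log2 units in that type, so the
    planted differentially active circuits of different types live on
    disjoint gene sets.  Counts are negative binomial with dispersion
    ``nb_dispersion`` and log-normal library factors.  Dropout zeroes a
    count with probability exp(-lambda * log1p(mu)^2) — rarer for abundant
    transcripts; lambda = 0 disables dropout entirely.

    Resistance: ``resistant_fraction`` of type-0 cells get the target mean
    scaled x0.1 and the compensator mean x5.
    """

    n_pathways: int = 5
    nodes_per_pathway: int = 10
    edge_density: float = 0.3
    p_inhibition: float = 0.15
    genes_per_node: tuple[int, int] = (1, 3)

    n_cell_types: int = 3
    cells_per_type: int = 60
    base_mean_log: float = 1.0
    base_mean_sigma: float = 0.6
    nb_dispersion: float = 2.0
    library_sigma: float = 0.3
    delta_log2: float = 2.0
    dropout_lambda: float = 0.2

    resistant_fraction: float = 0.15
    resistant_type: int = 0
    target_gene: str = "VEGFA"
    compensator_gene: str = "PDGFD"
    target_mean: float = 20.0
    compensator_mean: float = 2.0
    target_scale_resistant: float = 0.1
    compensator_scale_resistant: float = 5.0

    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_inhibition <= 1 or not 0 < self.edge_density <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.resistant_fraction <= 1:
            raise ValueError("resistant_fraction must lie in [0, 1]")
        if self.dropout_lambda < 0:
            raise ValueError("dropout_lambda must be >= 0")
        if self.n_pathways < 1 or self.nodes_per_pathway < 2:
            raise ValueError("need at least one pathway with two nodes")


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    cell_types: pd.Series  # cell id -> integer type
    planted: dict[int, list[str]]  # type -> planted circuit ids
    resistant: pd.Series  # cell id -> bool
    graphs: list[PathwayGraph]
    circuits: list[Circuit]
    pre_dropout: pd.DataFrame  # counts before dropout
    dropout_mask: pd.DataFrame  # True where a nonzero count was zeroed


def generate_pathways(
    cfg: SimulationConfig, seed: int | None = None, max_retries: int = 200
) -> list[PathwayGraph]:
    """Random signed DAG pathways with >= 1 source, >= 1 sink, all sinks reachable."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    graphs: list[PathwayGraph] = []
    gene_counter = 0
    for p in range(cfg.n_pathways):
        pid = f"PW{p + 1}"
        n = cfg.nodes_per_pathway
        for attempt in range(max_retries):
            edges_idx = [
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < cfg.edge_density
            ]
            g = nx.DiGraph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edges_idx)
            sources = [v for v in g if g.in_degree(v) == 0]
            sinks = [v for v in g if g.out_degree(v) == 0]
            if not edges_idx or not sources or not sinks:
                continue
            reach: set[int] = set()
            for s in sources:
                reach.add(s)
                reach |= nx.descendants(g, s)
            if all(t in reach for t in sinks) and set(sinks) != set(sources):
                break
        else:
            raise RuntimeError(
                f"could not generate a usable topology for {pid} after "
                f"{max_retries} attempts; increase edge_density"
            )

        nodes: dict[str, NodeSpec] = {}
        lo, hi = cfg.genes_per_node
        for v in range(n):
            nid = f"N{v + 1}"
            n_genes = int(rng.integers(lo, hi + 1))
            genes = tuple(f"SYN{gene_counter + i:04d}" for i in range(n_genes))
            gene_counter += n_genes
            nodes[nid] = NodeSpec(node_id=nid, genes=genes)
        if p == 0:
            # drug pathway: first receptor node carries target + compensator
            recv = f"N{min(sources) + 1}"
            nodes[recv] = NodeSpec(
                node_id=recv,
                genes=(cfg.target_gene, cfg.compensator_gene),
                label="target/compensator receptor",
            )
        edges = [
            (
                f"N{i + 1}",
                f"N{j + 1}",
                INHIBITION if rng.random() < cfg.p_inhibition else ACTIVATION,
            )
            for i, j in edges_idx
        ]
        graphs.append(PathwayGraph(pathway_id=pid, nodes=nodes, edges=edges))
    return graphs


def generate_cells(
    cfg: SimulationConfig,
    graphs: list[PathwayGraph],
    seed: int | None = None,
) -> tuple[GeneExpressionMatrix, SyntheticGroundTruth]:
    """Negative-binomial counts with planted structure, dropout and resistance."""
    rng = np.random.default_rng((cfg.seed if seed is None else seed) + 1)

    circuits: list[Circuit] = []
    for g in graphs:
        circuits.extend(extract_circuits(g))
    node_genes = {g.pathway_id: g.node_genes() for g in graphs}

    genes: list[str] = []
    seen: set[str] = set()
    for g in graphs:
        for spec in g.nodes.values():
            for sym in spec.genes:
                if sym not in seen:
                    seen.add(sym)
                    genes.append(sym)
    gene_pos = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)

    base_mean = np.exp(rng.normal(cfg.base_mean_log, cfg.base_mean_sigma, size=n_genes))
    if cfg.target_gene in gene_pos:
        base_mean[gene_pos[cfg.target_gene]] = cfg.target_mean
    if cfg.compensator_gene in gene_pos:
        base_mean[gene_pos[cfg.compensator_gene]] = cfg.compensator_mean

    # planting: each type gets one non-drug pathway (round-robin) whose genes
    # are shifted in that type; planted circuits therefore sit on disjoint
    # gene sets across types and the drug pathway stays unconfounded
    donor_pathways = [g for g in graphs[1:]] or list(graphs)
    planted: dict[int, list[str]] = {}
    type_mean = np.tile(base_mean[:, None], (1, cfg.n_cell_types))
    for t in range(cfg.n_cell_types):
        pw = donor_pathways[t % len(donor_pathways)]
        shifted: set[str] = set()
        planted[t] = []
        for c in circuits:
            if c.pathway_id != pw.pathway_id:
                continue
            planted[t].append(c.circuit_id)
            for nid in c.member_nodes:
                shifted.update(node_genes[c.pathway_id][nid])
        for sym in shifted:
            type_mean[gene_pos[sym], t] *= 2.0 ** cfg.delta_log2

    n_cells = cfg.n_cell_types * cfg.cells_per_type
    cell_ids = [f"C{i:04d}" for i in range(n_cells)]
    types = np.repeat(np.arange(cfg.n_cell_types), cfg.cells_per_type)
    cell_types = pd.Series(types, index=cell_ids, name="cell_type")

    resistant = pd.Series(False, index=cell_ids, name="resistant")
    type_cells = np.flatnonzero(types == cfg.resistant_type)
    n_res = int(round(cfg.resistant_fraction * len(type_cells)))
    res_idx = rng.choice(type_cells, size=n_res, replace=False)
    resistant.iloc[res_idx] = True

    lib = np.exp(rng.normal(0.0, cfg.library_sigma, size=n_cells))
    mu = type_mean[:, types] * lib[None, :]
    if cfg.target_gene in gene_pos:
        mu[gene_pos[cfg.target_gene], res_idx] *= cfg.target_scale_resistant
    if cfg.compensator_gene in gene_pos:
        mu[gene_pos[cfg.compensator_gene], res_idx] *= cfg.compensator_scale_resistant

    size = cfg.nb_dispersion
    counts = rng.negative_binomial(size, size / (size + mu)).astype(float)
    pre_dropout = counts.copy()

    if cfg.dropout_lambda > 0:
        p_drop = np.exp(-cfg.dropout_lambda * np.log1p(mu) ** 2)
        drop = rng.random(mu.shape) < p_drop
    else:
        drop = np.zeros(mu.shape, dtype=bool)
    counts[drop] = 0.0
    dropout_mask = drop & (pre_dropout > 0)

    expr = GeneExpressionMatrix(
        values=pd.DataFrame(counts, index=genes, columns=cell_ids), stage="counts"
    )
    truth = SyntheticGroundTruth(
        cell_types=cell_types,
        planted=planted,
        resistant=resistant,
        graphs=graphs,
        circuits=circuits,
        pre_dropout=pd.DataFrame(pre_dropout, index=genes, columns=cell_ids),
        dropout_mask=pd.DataFrame(dropout_mask, index=genes, columns=cell_ids),
    )
    return expr, truth


def generate_hallmark_annotation(
    graphs: list[PathwayGraph],
    circuits: list[Circuit],
    seed: int = 0,
) -> dict[str, frozenset[str]]:
    """Assign 1-2 canonical hallmarks to every effector gene (GMT-shaped)."""
    rng = np.random.default_rng(seed + 2)
    node_genes = {g.pathway_id: g.node_genes() for g in graphs}
    sets: dict[str, set[str]] = {h: set() for h in CANONICAL_HALLMARKS}
    for c in circuits:
        for sym in node_genes[c.pathway_id][c.effector_node]:
            n_h = int(rng.integers(1, 3))
            for h in rng.choice(len(CANONICAL_HALLMARKS), size=n_h, replace=False):
                sets[CANONICAL_HALLMARKS[h]].add(sym.upper())
    return {h: frozenset(g) for h, g in sets.items() if g}


def simulate_activity_groups(
    n_true: int = 20,
    n_null: int = 200,
    n_per_group: int = 100,
    delta: float = 0.3,
    sigma: float = 0.1,
    baseline: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, frozenset[str]]:
    """Direct activity-scale two-group simulation for power/FDR studies.

    Null circuits share a common mean in both groups; ``n_true`` circuits
    are shifted by ``delta`` in group 1.  Values are Gaussian with sd
    ``sigma`` and clipped to [0, 1].  Returns (activities, labels,
    planted-circuit ids).
    """
    rng = np.random.default_rng(seed)
    m = n_true + n_null
    n = 2 * n_per_group
    cells = [f"C{i:03d}" for i in range(n)]
    labels = pd.Series([0] * n_per_group + [1] * n_per_group, index=cells)
    means = np.full((m, n), baseline)
    means[:n_true, :n_per_group] += delta
    acts = np.clip(means + rng.normal(0.0, sigma, size=(m, n)), 0.0, 1.0)
    ids = [f"true{i:03d}" for i in range(n_true)] + [f"null{i:03d}" for i in range(n_null)]
    return (
        pd.DataFrame(acts, index=ids, columns=cells),
        labels,
        frozenset(ids[:n_true]),
    )


def write_fixture(cfg: SimulationConfig, outdir: str | Path) -> Path:
    """Write the full synthetic fixture set (expression, pathways, GMT, drugs, truth)."""
    from . import io as ccio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    graphs = generate_pathways(cfg)
    expr, truth = generate_cells(cfg, graphs)

    ccio.write_pathways(graphs, outdir / "pathway_edges.tsv", outdir / "pathway_nodes.tsv")
    ccio.write_expression(expr, outdir / "expression.tsv")
    ccio.write_expression_mtx(expr, outdir / "expression.mtx")

    gmt = generate_hallmark_annotation(graphs, truth.circuits, seed=cfg.seed)
    with open(outdir / "hallmarks.gmt", "w", encoding="utf-8") as fh:
        for name, members in gmt.items():
            fh.write("\t".join([name, "synthetic annotation", *sorted(members)]) + "\n")

    with open(outdir / "drugs.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug\tgene\taction\n")
        fh.write(f"TargetInhibitor\t{cfg.target_gene}\tinhibitor\n")
        fh.write(f"CompensatorAgonist\t{cfg.compensator_gene}\tagonist\n")

    truth_json = {
        "config": asdict(cfg),
        "cell_types": {c: int(t) for c, t in truth.cell_types.items()},
        "planted": {str(t): ids for t, ids in truth.planted.items()},
        "resistant": [c for c, r in truth.resistant.items() if r],
        "circuit_ids": [c.circuit_id for c in truth.circuits],
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_json, fh, indent=1)
    return outdir
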