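"""Signal propagation through signaling circuits.

Each node *n* holds a normalized expression value ``v_n`` in [0, 1] and
emits a signal

    S_n = v_n * (1 - prod_{s_a in A} (1 - s_a)) * prod_{s_i in I} (1 - s_i)

where *A* and *I* are the activating and inhibitory signals arriving on the
circuit's edges.  Receptor nodes receive one implicit activation of 1, so a
receptor transmits its own expression (``S_r = v_r``); a node with
inhibitors but no activating edge keeps an activation factor of 1 so that
inhibition alone can still gate it.  On acyclic circuits the recursion is
evaluated exactly in topological order; circuits with feedback loops are
iterated synchronously from all-zero signals to a fixed point.

All arithmetic is closed on [0, 1]: with inputs in the unit interval every
``S_n`` stays in the unit interval, raising ``v_n`` or any activating input
never decreases ``S_n``, and raising any inhibitory input never increases
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .pathways import ACTIVATION, Circuit, PathwayGraph

SummaryRule = Literal["mean", "min", "percentile90"]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to converge; carries the last residual."""

    def __init__(self, circuit_id: str, residual: float, max_iter: int):
        super().__init__(
            f"circuit {circuit_id}: no fixed point after {max_iter} iterations "
            f"(last max-abs-change {residual:.3g})"
        )
        self.residual = residual


@dataclass(frozen=True)
class PropagationSettings:
    """Knobs for turning expression into circuit activity.

    rule            how to summarize multi-gene nodes into one v_n
    missing_default v_n contribution of genes absent from the matrix
                    (None -> a circuit with zero measurable genes is an error)
    tol, max_iter   fixed-point stopping rule for circuits with cycles
    """

    rule: SummaryRule = "mean"
    missing_default: float | None = 0.5
    tol: float = 1e-6
    max_iter: int = 100

    def as_dict(self) -> dict:
        return {
            "rule": self.rule,
            "missing_default": self.missing_default,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }


@dataclass
class CircuitActivityMatrix:
    """Circuit x cell activity values in [0, 1] plus provenance."""

    values: pd.DataFrame  # rows = circuit ids, columns = cell ids
    settings: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and (np.isnan(arr).any() or arr.min() < 0 or arr.max() > 1):
            raise ValueError("activities must be finite and lie in [0, 1]")

    @property
    def circuit_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)


def node_value(
    expr_cell: Mapping[str, float],
    node,
    rule: SummaryRule = "mean",
    missing_default: float | None = 0.5,
) -> float:
    """Summarize a (possibly multi-gene) node into a single v_n.

    Gene symbols are matched case-insensitively; genes absent from
    ``expr_cell`` contribute ``missing_default``.
    """
    lookup = {str(k).upper(): v for k, v in expr_cell.items()}
    genes = node.genes if hasattr(node, "genes") else tuple(node)
    vals = []
    for g in genes:
        v = lookup.get(str(g).upper())
        if v is None:
            if missing_default is None:
                raise ValueError(f"gene {g!r} missing and no default value set")
            v = missing_default
        vals.append(float(v))
    return _summarize(np.asarray(vals, dtype=float), rule)


def _summarize(vals: np.ndarray, rule: SummaryRule) -> float:
    if rule == "mean":
        return float(vals.mean())
    if rule == "min":
        return float(vals.min())
    if rule == "percentile90":
        return float(np.quantile(vals, 0.9))
    raise ValueError(f"unknown summarization rule {rule!r}")


def _circuit_subgraph(circuit: Circuit) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(circuit.member_nodes)
    for src, tgt, sign in circuit.member_edges:
        g.add_edge(src, tgt, sign=sign)
    return g


def _node_update(
    g: nx.DiGraph,
    circuit: Circuit,
    node: str,
    v: np.ndarray,
    signal: dict[str, np.ndarray],
) -> np.ndarray:
    """One application of the recursion for ``node`` given upstream signals."""
    act = None  # product of (1 - s_a); None = no activating inputs yet
    inh = 1.0
    if node in circuit.receptor_nodes:
        act = 0.0  # implicit activation of 1
    for pred in g.predecessors(node):
        s = signal[pred]
        if g.edges[pred, node]["sign"] == ACTIVATION:
            act = (1.0 - s) if act is None else act * (1.0 - s)
        else:
            inh = inh * (1.0 - s)
    activation_factor = 1.0 if act is None else 1.0 - act
    return v * activation_factor * inh


def propagate(
    circuit: Circuit,
    node_values: Mapping[str, float | np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[float | np.ndarray, dict[str, float | np.ndarray]]:
    """Propagate node expression to the effector of one circuit.

    ``node_values`` maps every member node to v_n — a scalar, or an array to
    evaluate many cells at once (the recursion is elementwise).  Returns the
    effector signal and the full node -> S_n map.  Acyclic circuits are
    solved exactly in topological order; cyclic ones by synchronous
    fixed-point iteration from all-zero signals (raises
    :class:`ConvergenceError` if the max-abs change stays above ``tol``
    after ``max_iter`` sweeps).
    """
    g = _circuit_subgraph(circuit)
    vals = {n: np.asarray(node_values[n], dtype=float) for n in circuit.member_nodes}
    for n, v in vals.items():
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError(f"node value for {n!r} outside [0, 1]")

    if nx.is_directed_acyclic_graph(g):
        signal: dict[str, np.ndarray] = {}
        for n in nx.topological_sort(g):
            signal[n] = _node_update(g, circuit, n, vals[n], signal)
    else:
        shape = np.broadcast_shapes(*(v.shape for v in vals.values()))
        signal = {n: np.zeros(shape) for n in circuit.member_nodes}
        residual = np.inf
        for _ in range(max_iter):
            new = {n: _node_update(g, circuit, n, vals[n], signal) for n in signal}
            residual = max(
                float(np.max(np.abs(new[n] - signal[n]))) for n in signal
            )
            signal = new
            if residual < tol:
                break
        else:
            raise ConvergenceError(circuit.circuit_id, residual, max_iter)

    out = {n: (s if s.ndim else float(s)) for n, s in signal.items()}
    return out[circuit.effector_node], out


def activity_matrix(
    expr,
    circuits: Sequence[Circuit],
    graphs: Sequence[PathwayGraph] | dict[str, dict[str, tuple[str, ...]]],
    settings: PropagationSettings = PropagationSettings(),
) -> CircuitActivityMatrix:
    """Compute circuit x cell activities from a normalized expression matrix.

    ``expr`` is a :class:`~cellcircuit.preprocess.GeneExpressionMatrix` at
    stage ``normalized`` (or a bare genes x cells DataFrame with values in
    [0, 1]); ``graphs`` supplies the node -> genes tables, either as the
    pathway objects or as ``{pathway_id: {node_id: genes}}``.
    """
    df = expr.values if hasattr(expr, "values") and hasattr(expr, "stage") else expr
    if hasattr(expr, "stage") and expr.stage != "normalized":
        raise ValueError(f"expected a normalized matrix, got stage {expr.stage!r}")
    arr = df.to_numpy(dtype=float)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise ValueError("normalized expression must lie in [0, 1]")

    if isinstance(graphs, dict):
        node_genes = graphs
    else:
        node_genes = {g.pathway_id: g.node_genes() for g in graphs}

    gene_row = {str(g).upper(): i for i, g in enumerate(df.index)}
    n_cells = df.shape[1]
    md = settings.missing_default

    rows = np.empty((len(circuits), n_cells))
    n_cyclic = 0
    for ci, circuit in enumerate(circuits):
        table = node_genes[circuit.pathway_id]
        vals: dict[str, np.ndarray] = {}
        measurable = 0
        for nid in circuit.member_nodes:
            per_gene = []
            for gname in table[nid]:
                i = gene_row.get(str(gname).upper())
                if i is None:
                    if md is None:
                        continue
                    per_gene.append(np.full(n_cells, md))
                else:
                    measurable += 1
                    per_gene.append(arr[i])
            if not per_gene:
                raise ValueError(
                    f"circuit {circuit.circuit_id}: node {nid!r} has no measurable "
                    "genes and missing_default is unset"
                )
            stack = np.stack(per_gene)
            if settings.rule == "mean":
                vals[nid] = stack.mean(axis=0)
            elif settings.rule == "min":
                vals[nid] = stack.min(axis=0)
            elif settings.rule == "percentile90":
                vals[nid] = np.quantile(stack, 0.9, axis=0)
            else:
                raise ValueError(f"unknown summarization rule {settings.rule!r}")
        if measurable == 0:
            raise ValueError(
                f"circuit {circuit.circuit_id} references zero measurable genes"
            )
        g = _circuit_subgraph(circuit)
        if not nx.is_directed_acyclic_graph(g):
            n_cyclic += 1
        eff, _ = propagate(circuit, vals, tol=settings.tol, max_iter=settings.max_iter)
        rows[ci] = eff

    values = pd.DataFrame(
        rows, index=[c.circuit_id for c in circuits], columns=df.columns
    )
    return CircuitActivityMatrix(
        values=values,
        settings=settings.as_dict(),
        diagnostics={"n_circuits": len(circuits), "n_cyclic": n_cyclic},
    )
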