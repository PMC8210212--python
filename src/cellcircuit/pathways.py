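"""Signed pathway graphs and effector-centric signaling circuits.

A pathway is a signed directed graph whose nodes represent proteins or
protein families (one node may carry several gene symbols, e.g. a family of
growth-factor ligands that share the signal-transducer role).  A *circuit*
is the sub-network collecting every route from any receptor (source) node to
one effector (sink) node; it is the unit whose activity the propagation
model estimates.

The on-disk format is a plain-text stand-in for KEGG topologies: a TSV edge
list (``pathway_id  source  sign  target``) plus a TSV node table
(``pathway_id  node_id  genes`` with optional ``label``, ``is_receptor`` and
``is_effector`` columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

ACTIVATION = "activation"
INHIBITION = "inhibition"
_SIGNS = (ACTIVATION, INHIBITION)

_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "no", "n", ""}


class PathwayParseError(ValueError):
    """Raised when an edge or node file violates the format contract."""


@dataclass(frozen=True)
class NodeSpec:
    """A pathway node carrying one or more gene symbols."""

    node_id: str
    genes: tuple[str, ...]
    label: str = ""
    is_receptor: bool | None = None
    is_effector: bool | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"node {self.node_id!r} carries no genes")


@dataclass
class PathwayGraph:
    """A validated signed directed pathway graph."""

    pathway_id: str
    nodes: dict[str, NodeSpec]
    edges: list[tuple[str, str, str]]

    def __post_init__(self) -> None:
        for src, tgt, sign in self.edges:
            if sign not in _SIGNS:
                raise ValueError(f"unknown edge sign {sign!r} in {self.pathway_id}")
            if src not in self.nodes or tgt not in self.nodes:
                raise ValueError(
                    f"edge ({src!r}, {tgt!r}) references an undeclared node in "
                    f"pathway {self.pathway_id}"
                )
            if src == tgt:
                raise ValueError(f"self-loop on {src!r} in pathway {self.pathway_id}")

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph(pathway_id=self.pathway_id)
        g.add_nodes_from(self.nodes)
        for src, tgt, sign in self.edges:
            g.add_edge(src, tgt, sign=sign)
        return g

    def source_nodes(self) -> list[str]:
        g = self.to_networkx()
        return [n for n in self.nodes if g.in_degree(n) == 0]

    def sink_nodes(self) -> list[str]:
        g = self.to_networkx()
        return [n for n in self.nodes if g.out_degree(n) == 0]

    def node_genes(self) -> dict[str, tuple[str, ...]]:
        return {nid: spec.genes for nid, spec in self.nodes.items()}


@dataclass(frozen=True)
class Circuit:
    """All routes from any receptor to one effector within a pathway.

    ``member_nodes``/``member_edges`` are the union of nodes and edges lying
    on a directed route from some receptor to the effector.
    """

    circuit_id: str
    pathway_id: str
    effector_node: str
    receptor_nodes: frozenset[str]
    member_nodes: frozenset[str]
    member_edges: tuple[tuple[str, str, str], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.effector_node not in self.member_nodes:
            raise ValueError("effector must be a circuit member")
        if not self.receptor_nodes <= self.member_nodes:
            raise ValueError("receptors must be circuit members")


def _parse_bool(token: str, path: Path, lineno: int) -> bool:
    low = token.strip().lower()
    if low in _TRUE_TOKENS:
        return True
    if low in _FALSE_TOKENS:
        return False
    raise PathwayParseError(f"{path}:{lineno}: invalid boolean value {token!r}")


def _read_rows(path: Path) -> Iterable[tuple[int, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def load_pathways(edge_file: str | Path, node_file: str | Path) -> list[PathwayGraph]:
    """Parse edge and node TSV files into validated :class:`PathwayGraph` objects.

    Parse order is preserved: pathways appear in node-file order, nodes and
    edges in file order.  Malformed rows raise :class:`PathwayParseError`
    naming the file and line.
    """
    edge_file, node_file = Path(edge_file), Path(node_file)

    nodes_by_pathway: dict[str, dict[str, NodeSpec]] = {}
    rows = _read_rows(node_file)
    try:
        _, header = next(iter(rows))
    except StopIteration:
        raise PathwayParseError(f"{node_file}: empty node file") from None
    header = [h.strip() for h in header]
    required = ["pathway_id", "node_id", "genes"]
    for col in required:
        if col not in header:
            raise PathwayParseError(f"{node_file}: missing column {col!r}")
    idx = {name: header.index(name) for name in header}

    for lineno, fields in rows:
        if len(fields) < len(required):
            raise PathwayParseError(f"{node_file}:{lineno}: ragged row")

        def get(col: str, default: str = "") -> str:
            i = idx.get(col)
            return fields[i].strip() if i is not None and i < len(fields) else default

        pid, nid = get("pathway_id"), get("node_id")
        genes = tuple(g.strip() for g in get("genes").split(",") if g.strip())
        if not genes:
            raise PathwayParseError(f"{node_file}:{lineno}: node {nid!r} has no genes")
        pw = nodes_by_pathway.setdefault(pid, {})
        if nid in pw:
            raise PathwayParseError(
                f"{node_file}:{lineno}: duplicate node id {nid!r} in pathway {pid!r}"
            )
        is_rec = get("is_receptor", "")
        is_eff = get("is_effector", "")
        pw[nid] = NodeSpec(
            node_id=nid,
            genes=genes,
            label=get("label"),
            is_receptor=_parse_bool(is_rec, node_file, lineno) if is_rec else None,
            is_effector=_parse_bool(is_eff, node_file, lineno) if is_eff else None,
        )

    edges_by_pathway: dict[str, list[tuple[str, str, str]]] = {
        pid: [] for pid in nodes_by_pathway
    }
    rows = _read_rows(edge_file)
    try:
        _, eheader = next(iter(rows))
    except StopIteration:
        eheader = ["pathway_id", "source", "sign", "target"]
    eheader = [h.strip() for h in eheader]
    for col in ("pathway_id", "source", "sign", "target"):
        if col not in eheader:
            raise PathwayParseError(f"{edge_file}: missing column {col!r}")
    eidx = {name: eheader.index(name) for name in eheader}

    for lineno, fields in rows:
        if len(fields) < 4:
            raise PathwayParseError(f"{edge_file}:{lineno}: ragged row")
        pid = fields[eidx["pathway_id"]].strip()
        src = fields[eidx["source"]].strip()
        sign = fields[eidx["sign"]].strip()
        tgt = fields[eidx["target"]].strip()
        if pid not in nodes_by_pathway:
            raise PathwayParseError(
                f"{edge_file}:{lineno}: edge references undeclared pathway {pid!r}"
            )
        if sign not in _SIGNS:
            raise PathwayParseError(
                f"{edge_file}:{lineno}: unknown sign token {sign!r} "
                f"(expected one of {_SIGNS})"
            )
        for endpoint in (src, tgt):
            if endpoint not in nodes_by_pathway[pid]:
                raise PathwayParseError(
                    f"{edge_file}:{lineno}: edge references undeclared node "
                    f"{endpoint!r} in pathway {pid!r}"
                )
        edges_by_pathway[pid].append((src, tgt, sign))

    return [
        PathwayGraph(pathway_id=pid, nodes=nodes, edges=edges_by_pathway[pid])
        for pid, nodes in nodes_by_pathway.items()
    ]


def extract_circuits(
    graph: PathwayGraph,
    receptors: Sequence[str] | None = None,
    effectors: Sequence[str] | None = None,
) -> list[Circuit]:
    """Extract one effector-centric :class:`Circuit` per reachable effector.

    Receptors default to nodes flagged ``is_receptor`` in the node table, or
    to topological sources when no flags are present; effectors analogously
    default to flagged nodes or sinks.  A circuit's member set is the
    intersection of the nodes reachable from some receptor with the nodes
    from which the effector is reachable; for acyclic graphs this equals the
    union of all receptor-to-effector paths, and it extends that definition
    to graphs with feedback loops.  Effectors unreachable from every
    receptor are skipped with a warning.
    """
    g = graph.to_networkx()

    if receptors is None:
        flagged = [n for n, s in graph.nodes.items() if s.is_receptor]
        receptors = flagged if flagged else graph.source_nodes()
    else:
        receptors = list(receptors)
    if effectors is None:
        flagged = [n for n, s in graph.nodes.items() if s.is_effector]
        effectors = flagged if flagged else graph.sink_nodes()
    else:
        effectors = list(effectors)

    for nid in list(receptors) + list(effectors):
        if nid not in graph.nodes:
            raise ValueError(f"unknown node id {nid!r} in pathway {graph.pathway_id}")
    if not receptors:
        raise ValueError(
            f"pathway {graph.pathway_id} has no source nodes and no explicit "
            "receptor list: circuits are undefined"
        )

    downstream: set[str] = set()
    for r in receptors:
        downstream.add(r)
        downstream |= nx.descendants(g, r)

    circuits: list[Circuit] = []
    for eff in effectors:
        upstream = nx.ancestors(g, eff) | {eff}
        members = downstream & upstream
        circ_receptors = frozenset(r for r in receptors if r in members)
        if eff not in members or not circ_receptors:
            logger.warning(
                "pathway %s: effector %s unreachable from every receptor; skipped",
                graph.pathway_id,
                eff,
            )
            continue
        member_edges = tuple(
            (src, tgt, sign)
            for src, tgt, sign in graph.edges
            if src in members and tgt in members
        )
        circuits.append(
            Circuit(
                circuit_id=f"{graph.pathway_id}:{eff}",
                pathway_id=graph.pathway_id,
                effector_node=eff,
                receptor_nodes=circ_receptors,
                member_nodes=frozenset(members),
                member_edges=member_edges,
            )
        )
    return circuits


def circuit_gene_index(
    circuits: Sequence[Circuit],
    node_genes: dict[str, dict[str, tuple[str, ...]]],
) -> dict[str, frozenset[str]]:
    """Map circuit id -> set of member gene symbols (upper-cased).

    ``node_genes`` maps pathway id -> node id -> gene tuple (see
    :meth:`PathwayGraph.node_genes`).
    """
    out: dict[str, frozenset[str]] = {}
    for c in circuits:
        genes: set[str] = set()
        table = node_genes[c.pathway_id]
        for nid in c.member_nodes:
            genes.update(g.upper() for g in table[nid])
        out[c.circuit_id] = frozenset(genes)
    return out
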