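import numpy as np
import pytest

from cellcircuit.pathways import (
    ACTIVATION,
    INHIBITION,
    Circuit,
    NodeSpec,
    PathwayGraph,
)


def make_graph(pathway_id, edges, extra_nodes=(), genes=None):
    """Build a PathwayGraph from (src, tgt, sign) triples; one gene per node."""
    node_ids = {n for e in edges for n in e[:2]} | set(extra_nodes)
    genes = genes or {}
    nodes = {
        n: NodeSpec(node_id=n, genes=tuple(genes.get(n, (n,))))
        for n in sorted(node_ids)
    }
    return PathwayGraph(pathway_id=pathway_id, nodes=nodes, edges=list(edges))


def single_node_circuit(node_id="X"):
    return Circuit(
        circuit_id=f"P:{node_id}",
        pathway_id="P",
        effector_node=node_id,
        receptor_nodes=frozenset({node_id}),
        member_nodes=frozenset({node_id}),
        member_edges=(),
    )


def random_dag(rng, n_nodes, density=0.4, p_inhibition=0.3):
    """Random signed DAG over ordered nodes with at least one edge."""
    while True:
        edges = []
        for i in range(n_nodes):
            for j in range(i + 1, n_nodes):
                if rng.random() < density:
                    sign = INHIBITION if rng.random() < p_inhibition else ACTIVATION
                    edges.append((f"N{i}", f"N{j}", sign))
        if edges:
            return make_graph("P", edges, extra_nodes=[f"N{i}" for i in range(n_nodes)])


def brute_force_signal(circuit, node_values):
    """Independent recursive evaluation of the propagation rule on a DAG.

    Plain dict-based memoized recursion; shares no code with the package's
    topological/fixed-point implementations.
    """
    preds = {}
    for src, tgt, sign in circuit.member_edges:
        preds.setdefault(tgt, []).append((src, sign))
    memo = {}

    def s(n):
        if n in memo:
            return memo[n]
        acts, inhs = [], []
        if n in circuit.receptor_nodes:
            acts.append(1.0)
        for src, sign in preds.get(n, []):
            (acts if sign == ACTIVATION else inhs).append(s(src))
        act_factor = 1.0
        if acts:
            prod = 1.0
            for a in acts:
                prod *= 1.0 - a
            act_factor = 1.0 - prod
        inh_factor = 1.0
        for i in inhs:
            inh_factor *= 1.0 - i
        memo[n] = node_values[n] * act_factor * inh_factor
        return memo[n]

    return s(circuit.effector_node), {n: s(n) for n in circuit.member_nodes}


def brute_force_members(graph, receptors, effector):
    """Union of nodes over exhaustive simple-path enumeration (oracle)."""
    import networkx as nx

    g = graph.to_networkx()
    members = set()
    for r in receptors:
        if r == effector:
            members.add(r)
        for path in nx.all_simple_paths(g, r, effector):
            members.update(path)
    return members


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)
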