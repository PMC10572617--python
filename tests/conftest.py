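"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest

from pathact.graphs import Circuit, PathwayGraph, PathwayNode, SignedEdge


def make_circuit(
    edges: list[tuple[str, str, int]],
    nodes: list[str] | None = None,
    effector: str | None = None,
    pathway_id: str = "T",
) -> Circuit:
    """Build a circuit directly from a signed edge list (genes irrelevant)."""
    if nodes is None:
        nodes = sorted({n for e in edges for n in e[:2]})
    if effector is None:
        with_out = {src for src, _, _ in edges}
        sinks = [n for n in nodes if n not in with_out]
        assert len(sinks) == 1, "ambiguous effector; pass explicitly"
        effector = sinks[0]
    return Circuit(
        circuit_id=f"{pathway_id}:{effector}",
        pathway_id=pathway_id,
        effector=effector,
        member_nodes=frozenset(nodes),
        member_edges=tuple(SignedEdge(s, t, sg) for s, t, sg in edges),
        node_genes={n: () for n in nodes},
        effector_genes=(),
    )


def random_dag_circuit(
    rng: np.random.Generator,
    n_nodes: int,
    inhibition_prob: float = 0.3,
) -> Circuit:
    """Random acyclic circuit in which every node reaches the last node."""
    names = [f"N{i:02d}" for i in range(n_nodes)]
    edges: list[tuple[str, str, int]] = []
    seen = set()
    for i in range(n_nodes - 1):
        targets = {int(j) for j in rng.integers(i + 1, n_nodes, size=rng.integers(1, 3))}
        for j in targets:
            if (i, j) not in seen:
                seen.add((i, j))
                sign = -1 if rng.random() < inhibition_prob else 1
                edges.append((names[i], names[j], sign))
    return make_circuit(edges, nodes=names, effector=names[-1])


def random_cyclic_circuit(
    rng: np.random.Generator,
    n_nodes: int,
    inhibition_prob: float = 0.3,
    n_back: int = 2,
) -> Circuit:
    """Random circuit with back-edges (cycles); effector stays the last node."""
    base = random_dag_circuit(rng, n_nodes, inhibition_prob)
    names = sorted(base.member_nodes)
    edges = [(e.source, e.target, e.sign) for e in base.member_edges]
    seen = {(s, t) for s, t, _ in edges}
    for _ in range(n_back):
        j = int(rng.integers(1, n_nodes - 1))
        i = int(rng.integers(0, j))
        if (names[j], names[i]) not in seen:
            seen.add((names[j], names[i]))
            sign = -1 if rng.random() < inhibition_prob else 1
            edges.append((names[j], names[i], sign))
    return make_circuit(edges, nodes=names, effector=names[-1])


def random_node_values(rng: np.random.Generator, circuit: Circuit, n_samples: int = 3) -> pd.DataFrame:
    order = sorted(circuit.member_nodes)
    return pd.DataFrame(rng.uniform(size=(len(order), n_samples)), index=order,
                        columns=[f"s{i}" for i in range(n_samples)])


def recursive_signal(circuit: Circuit, node_vals: pd.DataFrame) -> np.ndarray:
    """Independent oracle: memoized direct recursion of the propagation rule
    (valid on acyclic circuits only)."""
    act_in: dict[str, list[str]] = {n: [] for n in circuit.member_nodes}
    inh_in: dict[str, list[str]] = {n: [] for n in circuit.member_nodes}
    for e in circuit.member_edges:
        (act_in if e.sign > 0 else inh_in)[e.target].append(e.source)
    memo: dict[str, np.ndarray] = {}

    def s(n: str) -> np.ndarray:
        if n not in memo:
            v = node_vals.loc[n].to_numpy(dtype=float)
            if act_in[n]:
                act = 1.0 - np.prod([1.0 - s(a) for a in act_in[n]], axis=0)
            else:
                act = 1.0
            inh = np.prod([1.0 - s(i) for i in inh_in[n]], axis=0) if inh_in[n] else 1.0
            memo[n] = v * act * inh
        return memo[n]

    return s(circuit.effector)


@pytest.fixture
def chain_graph() -> PathwayGraph:
    """A -> B -> C chain with one function node hanging off the effector."""
    nodes = {
        "A": PathwayNode("A", ("g1",), "A"),
        "B": PathwayNode("B", ("g2", "g3"), "B"),
        "C": PathwayNode("C", ("g4",), "C"),
        "F": PathwayNode("F", (), "apoptosis", is_function=True),
    }
    edges = [SignedEdge("A", "B", 1), SignedEdge("B", "C", 1), SignedEdge("C", "F", 1)]
    return PathwayGraph(pathway_id="P1", name="chain", nodes=nodes, edges=edges)


@pytest.fixture
def node_table() -> io.StringIO:
    return io.StringIO(
        "pathway_id\tnode_id\tlabel\tgenes\tis_function\n"
        "P1\tA\tA\tg1\t0\n"
        "P1\tB\tB\tg2;g3\t0\n"
        "P1\tC\tC\tg4\t0\n"
        "P1\tF\tapoptosis\t\t1\n"
    )


@pytest.fixture
def edge_table() -> io.StringIO:
    return io.StringIO(
        "pathway_id\tsource\ttarget\tsign\n"
        "P1\tA\tB\tactivates\n"
        "P1\tB\tC\t+1\n"
        "P1\tC\tF\t+1\n"
    )
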