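"""Signal propagation through single-effector circuits.

Each node n carries a unit-interval value v_n summarizing its genes' scaled
expression (a proxy for active-protein presence).  The signal at a node is

    S_n = v_n * (1 - prod_{a in A}(1 - s_a)) * prod_{i in I}(1 - s_i)

where A and I are the incoming activation and inhibition signals.  Nodes with
no incoming activation edge (receptors) take activation term 1, so they emit
their own value; the empty inhibition product is 1.  The circuit activity is
the signal at the effector node.

Acyclic circuits are solved exactly in one topological sweep; cyclic circuits
by Jacobi iteration from S0 = v (flagged if the tolerance is not reached
within ``max_iter``).  Since v in [0, 1], every S stays in [0, 1].

Raw effector signals shrink geometrically with circuit depth (a chain of k
nodes at value 0.5 yields 0.5**k), so a per-circuit positive constant
normalization makes circuits of different lengths comparable; it cannot
change any sample ordering or downstream test statistic that is scale-free.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graphs import Circuit, CircuitCatalog, PathwayGraph

logger = logging.getLogger(__name__)

__all__ = [
    "PropagationConfig",
    "ActivityMatrix",
    "node_values",
    "propagate_circuit",
    "normalize_path_activity",
    "compute_activity_matrix",
]

_SUMMARIES = ("mean", "median", "percentile")
_LENGTH_NORMS = ("geometric", "reference", "none")


@dataclass(frozen=True)
class PropagationConfig:
    """Solver and summarization controls.

    tol/max_iter govern the Jacobi iteration on cyclic circuits;
    node_summary collapses multi-gene nodes (mean by default);
    length_norm selects the per-circuit depth correction.
    """

    tol: float = 1e-6
    max_iter: int = 1000
    node_summary: str = "mean"
    percentile: float = 90.0
    length_norm: str = "geometric"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.node_summary not in _SUMMARIES:
            raise ValueError(f"node_summary must be one of {_SUMMARIES}")
        if self.length_norm not in _LENGTH_NORMS:
            raise ValueError(f"length_norm must be one of {_LENGTH_NORMS}")


@dataclass
class ActivityMatrix:
    """Circuits x samples activity values plus per-circuit convergence flags."""

    values: pd.DataFrame
    converged: pd.Series
    raw: pd.DataFrame | None = None
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def circuit_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# node values
# ---------------------------------------------------------------------------


def _summarize(block: np.ndarray, config: PropagationConfig) -> np.ndarray:
    if config.node_summary == "mean":
        return block.mean(axis=0)
    if config.node_summary == "median":
        return np.median(block, axis=0)
    return np.percentile(block, config.percentile, axis=0)


def _node_values_from_genes(
    scaled: pd.DataFrame,
    node_genes: dict[str, tuple[str, ...]],
    config: PropagationConfig,
) -> pd.DataFrame:
    """nodes x samples value matrix from gene-level scaled expression."""
    n_samples = scaled.shape[1]
    rows = {}
    for nid in sorted(node_genes):
        genes = node_genes[nid]
        if not genes:
            # empty-gene relay (e.g. metabolite): transparent, value 1
            rows[nid] = np.ones(n_samples)
            continue
        missing = [g for g in genes if g not in scaled.index]
        if missing:
            raise KeyError(f"node {nid!r}: genes missing after imputation: {missing}")
        rows[nid] = _summarize(scaled.loc[list(genes)].to_numpy(dtype=float), config)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=scaled.columns)
    if ((out < -1e-12) | (out > 1 + 1e-12)).to_numpy().any():
        raise ValueError("node values outside [0, 1]; rescale expression first")
    return out.clip(0.0, 1.0)


def node_values(
    scaled: pd.DataFrame,
    graph: PathwayGraph,
    config: PropagationConfig = PropagationConfig(),
) -> pd.DataFrame:
    """Per-node values for all non-function nodes of a pathway graph."""
    node_genes = {nid: n.genes for nid, n in graph.nodes.items() if not n.is_function}
    return _node_values_from_genes(scaled, node_genes, config)


# ---------------------------------------------------------------------------
# propagation
# ---------------------------------------------------------------------------


def _incoming(circuit: Circuit, order: list[str]) -> tuple[list[list[int]], list[list[int]]]:
    idx = {nid: i for i, nid in enumerate(order)}
    act: list[list[int]] = [[] for _ in order]
    inh: list[list[int]] = [[] for _ in order]
    for e in circuit.member_edges:
        (act if e.sign > 0 else inh)[idx[e.target]].append(idx[e.source])
    return act, inh


def _apply_rule(
    i: int, v: np.ndarray, s: np.ndarray, act: list[list[int]], inh: list[list[int]]
) -> np.ndarray:
    if act[i]:
        act_term = 1.0 - np.prod(1.0 - s[act[i]], axis=0)
    else:
        act_term = 1.0  # receptor: implicit incoming signal 1
    inh_term = np.prod(1.0 - s[inh[i]], axis=0) if inh[i] else 1.0
    return v[i] * act_term * inh_term


def _circuit_digraph(circuit: Circuit) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(circuit.member_nodes)
    g.add_edges_from((e.source, e.target) for e in circuit.member_edges)
    return g


def propagate_circuit(
    circuit: Circuit,
    node_vals: pd.DataFrame,
    config: PropagationConfig = PropagationConfig(),
    method: str = "auto",
    return_all_nodes: bool = False,
):
    """Per-sample raw effector signal for one circuit.

    ``method``: "auto" uses a topological sweep when the circuit is acyclic
    and Jacobi iteration otherwise; "jacobi" forces iteration (used by the
    equivalence tests).  Returns (signal, converged) or, with
    ``return_all_nodes``, (node signal DataFrame, converged).
    """
    order = sorted(circuit.member_nodes)
    missing = [nid for nid in order if nid not in node_vals.index]
    if missing:
        raise KeyError(f"circuit {circuit.circuit_id}: nodes without values: {missing}")
    v = node_vals.loc[order].to_numpy(dtype=float)
    act, inh = _incoming(circuit, order)
    g = _circuit_digraph(circuit)
    acyclic = nx.is_directed_acyclic_graph(g)

    if method == "auto":
        method = "topo" if acyclic else "jacobi"
    if method == "topo" and not acyclic:
        raise ValueError("topological sweep requires an acyclic circuit")

    if method == "topo":
        idx = {nid: i for i, nid in enumerate(order)}
        s = np.empty_like(v)
        for nid in nx.lexicographical_topological_sort(g):
            i = idx[nid]
            s[i] = _apply_rule(i, v, s, act, inh)
        converged = True
    elif method == "jacobi":
        s = v.copy()
        converged = False
        for _ in range(config.max_iter):
            s_new = np.empty_like(s)
            for i in range(len(order)):
                s_new[i] = _apply_rule(i, v, s, act, inh)
            delta = np.max(np.abs(s_new - s)) if s.size else 0.0
            s = s_new
            if delta < config.tol:
                converged = True
                break
        if not converged:
            logger.warning("circuit %s: Jacobi iteration hit max_iter", circuit.circuit_id)
    else:
        raise ValueError(f"unknown method {method!r}")

    if return_all_nodes:
        return pd.DataFrame(s, index=order, columns=node_vals.columns), converged
    eff_i = order.index(circuit.effector)
    return s[eff_i], converged


# ---------------------------------------------------------------------------
# length normalization
# ---------------------------------------------------------------------------


def _activation_subgraph(circuit: Circuit) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(circuit.member_nodes)
    g.add_edges_from((e.source, e.target) for e in circuit.member_edges if e.sign > 0)
    return g


def _receptors(circuit: Circuit) -> set[str]:
    with_act_in = {e.target for e in circuit.member_edges if e.sign > 0}
    return set(circuit.member_nodes) - with_act_in


def _longest_activation_path_nodes(circuit: Circuit) -> int:
    """Node count of the longest receptor->effector activation-only path.

    Cycles are handled by condensing strongly connected components (each SCC
    contributes its node count), which keeps the measure well defined and
    deterministic.
    """
    g = _activation_subgraph(circuit)
    receptors = _receptors(circuit)
    cond = nx.condensation(g)
    size = {c: len(cond.nodes[c]["members"]) for c in cond.nodes}
    comp_of = {nid: c for c in cond.nodes for nid in cond.nodes[c]["members"]}
    eff_c = comp_of[circuit.effector]
    start = {comp_of[r] for r in receptors}
    # longest weighted path to eff_c over the condensation DAG
    best: dict[int, float] = {c: (size[c] if c in start else -np.inf) for c in cond.nodes}
    for c in nx.topological_sort(cond):
        if best[c] == -np.inf:
            continue
        for succ in cond.successors(c):
            cand = best[c] + size[succ]
            if cand > best[succ]:
                best[succ] = cand
    length = best[eff_c]
    if not np.isfinite(length):
        length = size[eff_c]  # effector not activation-reachable from a receptor
    return int(length)


def _reference_factor(circuit: Circuit, config: PropagationConfig) -> float:
    """Raw signal at saturation: v=1 everywhere except purely inhibitory
    branches (nodes with no activation-only path to the effector), set to 0."""
    g_act = _activation_subgraph(circuit)
    reaches_by_activation = nx.ancestors(g_act, circuit.effector) | {circuit.effector}
    v_ref = pd.DataFrame(
        {
            "_ref": [1.0 if nid in reaches_by_activation else 0.0 for nid in sorted(circuit.member_nodes)]
        },
        index=sorted(circuit.member_nodes),
    )
    sig, _ = propagate_circuit(circuit, v_ref, config)
    ref = float(sig[0])
    return ref if ref > 1e-12 else 1.0


def normalize_path_activity(
    raw: np.ndarray,
    circuit: Circuit,
    config: PropagationConfig = PropagationConfig(),
) -> np.ndarray:
    """Divide raw effector signal by a per-circuit positive constant.

    geometric (default): 0.5**L with L the longest activation path length in
    nodes; reference: saturation signal (all values 1, inhibitory branches 0);
    none: identity.  Sample ordering is always preserved.
    """
    raw = np.asarray(raw, dtype=float)
    if config.length_norm == "none":
        return raw
    if config.length_norm == "geometric":
        L = _longest_activation_path_nodes(circuit)
        return raw / (0.5 ** L)
    return raw / _reference_factor(circuit, config)


# ---------------------------------------------------------------------------
# full matrix
# ---------------------------------------------------------------------------


def compute_activity_matrix(
    catalog: CircuitCatalog,
    scaled: pd.DataFrame,
    config: PropagationConfig = PropagationConfig(),
) -> ActivityMatrix:
    """node values -> propagation -> length normalization for every circuit.

    Per-circuit failures are collected into ``failures``; the call fails only
    if no circuit could be computed.
    """
    if len(catalog) == 0:
        raise ValueError("empty circuit catalog")
    rows, raw_rows, conv, failures = {}, {}, {}, {}
    for circuit in catalog:
        try:
            nv = _node_values_from_genes(scaled, dict(circuit.node_genes), config)
            sig, ok = propagate_circuit(circuit, nv, config)
            rows[circuit.circuit_id] = normalize_path_activity(sig, circuit, config)
            raw_rows[circuit.circuit_id] = sig
            conv[circuit.circuit_id] = ok
        except Exception as exc:  # noqa: BLE001 - aggregated into report
            failures[circuit.circuit_id] = str(exc)
    if not rows:
        raise RuntimeError(f"all circuits failed: {failures}")
    if failures:
        logger.warning("activity computation failed for %d circuits", len(failures))
    values = pd.DataFrame.from_dict(rows, orient="index", columns=scaled.columns)
    raw = pd.DataFrame.from_dict(raw_rows, orient="index", columns=scaled.columns)
    order = [c.circuit_id for c in catalog if c.circuit_id in rows]
    return ActivityMatrix(
        values=values.loc[order],
        converged=pd.Series(conv).loc[order],
        raw=raw.loc[order],
        failures=failures,
    )
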