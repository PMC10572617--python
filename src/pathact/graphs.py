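"""Signed directed pathway graphs and their single-effector circuits.

A signaling pathway is modeled as a directed graph whose nodes hold one or
more genes (protein complexes / gene families) and whose edges carry a sign:
+1 for activation, -1 for inhibition.  Terminal "function" nodes are
annotation-only labels of cellular outcomes; the signal is never propagated
through them.  An *effector* is a node whose outgoing edges (if any) lead only
to function nodes; the *circuit* of an effector is the sub-graph of all nodes
with a directed path to it.  Circuits are the unit at which activity,
differential and survival statistics are computed downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayNode",
    "SignedEdge",
    "PathwayGraph",
    "Circuit",
    "CircuitCatalog",
    "PathwayParseError",
    "parse_pathway",
    "parse_pathways",
    "find_effectors",
    "extract_circuits",
    "validate_graph",
]

#: accepted sign tokens in edge tables
SIGN_TOKENS: Mapping[str, int] = {
    "1": 1,
    "+1": 1,
    "-1": -1,
    "activation": 1,
    "activates": 1,
    "inhibition": -1,
    "inhibits": -1,
}


class PathwayParseError(ValueError):
    """Raised on malformed node/edge tables (names the offending row)."""


@dataclass(frozen=True)
class PathwayNode:
    """A pathway node: a gene set (possibly empty) with a display label.

    ``is_function`` marks annotation-only terminal nodes (cellular functions)
    that are never propagated through.
    """

    node_id: str
    genes: tuple[str, ...] = ()
    label: str = ""
    is_function: bool = False

    def __post_init__(self) -> None:
        if not self.node_id:
            raise ValueError("node_id must be non-empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in node {self.node_id!r}")


@dataclass(frozen=True)
class SignedEdge:
    """A directed signed interaction: +1 activation, -1 inhibition."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in (1, -1):
            raise ValueError(f"edge sign must be +1 or -1, got {self.sign!r}")


@dataclass
class PathwayGraph:
    """A signed directed pathway graph.

    ``nodes`` maps node_id -> :class:`PathwayNode`; ``edges`` is the list of
    :class:`SignedEdge` (parallel edges of opposite sign are legal).
    """

    pathway_id: str
    name: str = ""
    nodes: dict[str, PathwayNode] = field(default_factory=dict)
    edges: list[SignedEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.nodes:
            raise ValueError(f"pathway {self.pathway_id!r} has no nodes")
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise ValueError(
                        f"edge {e.source}->{e.target} references undeclared "
                        f"node {endpoint!r} in pathway {self.pathway_id!r}"
                    )

    @property
    def genes(self) -> set[str]:
        return {g for n in self.nodes.values() for g in n.genes}

    def signaling_subgraph(self) -> nx.DiGraph:
        """Directed graph over non-function nodes (signal-carrying part).

        Parallel opposite-sign edges collapse to one arc; signs live on the
        edge lists kept by :func:`extract_circuits`, not here.
        """
        g = nx.DiGraph()
        for nid, node in self.nodes.items():
            if not node.is_function:
                g.add_node(nid)
        for e in self.edges:
            if not self.nodes[e.source].is_function and not self.nodes[e.target].is_function:
                g.add_edge(e.source, e.target)
        return g


@dataclass(frozen=True)
class Circuit:
    """A single-effector circuit: every member node reaches the effector.

    ``node_genes`` carries the gene membership of every member node so that
    activity propagation needs no access back to the parent graph;
    ``functions`` lists the labels of function nodes attached to the effector.
    """

    circuit_id: str
    pathway_id: str
    effector: str
    member_nodes: frozenset[str]
    member_edges: tuple[SignedEdge, ...]
    node_genes: Mapping[str, tuple[str, ...]]
    effector_genes: tuple[str, ...]
    functions: tuple[str, ...] = ()

    @property
    def genes(self) -> set[str]:
        return {g for gs in self.node_genes.values() for g in gs}


@dataclass
class CircuitCatalog:
    """An indexed collection of circuits (unique circuit_ids)."""

    circuits: list[Circuit]

    def __post_init__(self) -> None:
        ids = [c.circuit_id for c in self.circuits]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate circuit_ids in catalog")
        self._index = {c.circuit_id: c for c in self.circuits}

    def __len__(self) -> int:
        return len(self.circuits)

    def __iter__(self):
        return iter(self.circuits)

    def __getitem__(self, circuit_id: str) -> Circuit:
        return self._index[circuit_id]

    def __contains__(self, circuit_id: str) -> bool:
        return circuit_id in self._index

    @property
    def circuit_ids(self) -> list[str]:
        return [c.circuit_id for c in self.circuits]

    @property
    def all_genes(self) -> set[str]:
        return {g for c in self.circuits for g in c.genes}

    def to_frame(self) -> pd.DataFrame:
        """Export as a table: circuit_id, pathway_id, effector, sizes, genes."""
        rows = [
            {
                "circuit_id": c.circuit_id,
                "pathway_id": c.pathway_id,
                "effector": c.effector,
                "n_nodes": len(c.member_nodes),
                "n_edges": len(c.member_edges),
                "genes": ";".join(sorted(c.genes)),
            }
            for c in self.circuits
        ]
        return pd.DataFrame(rows, columns=["circuit_id", "pathway_id", "effector", "n_nodes", "n_edges", "genes"])


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

_NODE_COLS = ["pathway_id", "node_id", "label", "genes", "is_function"]
_EDGE_COLS = ["pathway_id", "source", "target", "sign"]

_TRUE_TOKENS = {"1", "true", "yes"}
_FALSE_TOKENS = {"0", "false", "no", ""}


def _read_table(table, columns: Sequence[str], what: str) -> pd.DataFrame:
    df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise PathwayParseError(f"{what} table missing columns: {missing}")
    return df


def _parse_bool(token: str, row: int) -> bool:
    t = str(token).strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    raise PathwayParseError(f"node table row {row}: bad is_function token {token!r}")


def parse_pathways(node_table, edge_table, *, allow_self_loops: bool = False) -> list[PathwayGraph]:
    """Parse node and edge tables (TSV paths or buffers) into pathway graphs.

    Node table columns: ``pathway_id  node_id  label  genes  is_function``
    with ``genes`` ";"-separated.  Edge table columns:
    ``pathway_id  source  target  sign`` with sign one of
    {+1, -1, activation, inhibition, activates, inhibits}.

    Self-loops are rejected unless ``allow_self_loops`` (then dropped with a
    warning): the propagation rule has no convention for them.
    """
    nodes_df = _read_table(node_table, _NODE_COLS, "node")
    edges_df = _read_table(edge_table, _EDGE_COLS, "edge")

    graphs: dict[str, PathwayGraph] = {}
    node_map: dict[str, dict[str, PathwayNode]] = {}
    for i, row in nodes_df.iterrows():
        pid = row["pathway_id"]
        nid = row["node_id"]
        pernodes = node_map.setdefault(pid, {})
        if nid in pernodes:
            raise PathwayParseError(f"node table row {i + 2}: duplicate node_id {nid!r} in pathway {pid!r}")
        genes = tuple(g for g in str(row["genes"]).split(";") if g)
        pernodes[nid] = PathwayNode(
            node_id=nid,
            genes=genes,
            label=row["label"],
            is_function=_parse_bool(row["is_function"], i + 2),
        )

    edge_map: dict[str, list[SignedEdge]] = {pid: [] for pid in node_map}
    for i, row in edges_df.iterrows():
        pid = row["pathway_id"]
        if pid not in node_map:
            raise PathwayParseError(f"edge table row {i + 2}: unknown pathway_id {pid!r}")
        token = str(row["sign"]).strip().lower()
        if token not in SIGN_TOKENS:
            raise PathwayParseError(f"edge table row {i + 2}: unknown sign token {row['sign']!r}")
        src, tgt = row["source"], row["target"]
        for endpoint in (src, tgt):
            if endpoint not in node_map[pid]:
                raise PathwayParseError(
                    f"edge table row {i + 2}: edge {src}->{tgt} references undeclared node {endpoint!r}"
                )
        if src == tgt:
            if allow_self_loops:
                logger.warning("dropping self-loop on %s in pathway %s", src, pid)
                continue
            raise PathwayParseError(f"edge table row {i + 2}: self-loop on node {src!r}")
        edge_map[pid].append(SignedEdge(src, tgt, SIGN_TOKENS[token]))

    for pid, pernodes in node_map.items():
        graphs[pid] = PathwayGraph(pathway_id=pid, name=pid, nodes=pernodes, edges=edge_map[pid])
    return [graphs[pid] for pid in sorted(graphs)]


def parse_pathway(node_table, edge_table, **kwargs) -> PathwayGraph:
    """Parse tables containing exactly one pathway."""
    graphs = parse_pathways(node_table, edge_table, **kwargs)
    if len(graphs) != 1:
        raise PathwayParseError(f"expected one pathway, found {len(graphs)}")
    return graphs[0]


# ---------------------------------------------------------------------------
# effectors and circuits
# ---------------------------------------------------------------------------


def find_effectors(graph: PathwayGraph) -> list[str]:
    """Effector nodes: non-function nodes whose out-edges lead only to
    function nodes (or nowhere).  Sorted by node_id for determinism."""
    out_to_signal: dict[str, bool] = {
        nid: False for nid, n in graph.nodes.items() if not n.is_function
    }
    for e in graph.edges:
        if graph.nodes[e.source].is_function or graph.nodes[e.target].is_function:
            continue
        if e.source != e.target:
            out_to_signal[e.source] = True
    effectors = sorted(nid for nid, has_out in out_to_signal.items() if not has_out)
    if not effectors:
        logger.warning("pathway %s has no effectors (pure cycle?)", graph.pathway_id)
    return effectors


def extract_circuits(graph: PathwayGraph) -> CircuitCatalog:
    """One circuit per effector: all non-function nodes with a directed path
    to the effector, with the induced signed edges.  Cycles are retained."""
    sub = graph.signaling_subgraph()
    circuits = []
    for eff in find_effectors(graph):
        members = frozenset(nx.ancestors(sub, eff) | {eff})
        member_edges = tuple(
            e
            for e in graph.edges
            if e.source in members and e.target in members and e.source != e.target
        )
        functions = tuple(
            sorted(
                graph.nodes[e.target].label or e.target
                for e in graph.edges
                if e.source == eff and graph.nodes[e.target].is_function
            )
        )
        node_genes = {nid: graph.nodes[nid].genes for nid in sorted(members)}
        circuits.append(
            Circuit(
                circuit_id=f"{graph.pathway_id}:{eff}",
                pathway_id=graph.pathway_id,
                effector=eff,
                member_nodes=members,
                member_edges=member_edges,
                node_genes=node_genes,
                effector_genes=graph.nodes[eff].genes,
                functions=functions,
            )
        )
    return CircuitCatalog(circuits)


def positive_influence_nodes(circuit: Circuit) -> set[str]:
    """Member nodes whose value influences the effector monotonically upward.

    A node qualifies when every directed path from it to the effector crosses
    an even number of inhibition edges (computed by parity-labelled
    reachability, so cycles are handled).  Raising such a node's value can
    never decrease the effector signal under the propagation rule; nodes with
    mixed-parity paths are excluded as ambiguous.
    """
    out: dict[str, list[tuple[str, int]]] = {n: [] for n in circuit.member_nodes}
    for e in circuit.member_edges:
        out[e.source].append((e.target, 0 if e.sign > 0 else 1))
    eff = circuit.effector
    positive = set()
    for start in circuit.member_nodes:
        seen = {(start, 0)}
        stack = [(start, 0)]
        parities = set()
        while stack:
            node, par = stack.pop()
            if node == eff:
                parities.add(par)
            for nxt, flip in out[node]:
                state = (nxt, par ^ flip)
                if state not in seen:
                    seen.add(state)
                    stack.append(state)
        if parities == {0}:
            positive.add(start)
    return positive


def merge_catalogs(catalogs: Iterable[CircuitCatalog]) -> CircuitCatalog:
    """Concatenate per-pathway catalogs into one."""
    circuits: list[Circuit] = []
    for cat in catalogs:
        circuits.extend(cat.circuits)
    return CircuitCatalog(circuits)


def validate_graph(graph: PathwayGraph) -> list[str]:
    """Diagnostics (non-fatal): duplicate same-sign edges, non-gene nodes,
    nodes unreachable from/to any effector, self-loops."""
    diagnostics: list[str] = []
    seen: dict[tuple[str, str, int], int] = {}
    for e in graph.edges:
        key = (e.source, e.target, e.sign)
        seen[key] = seen.get(key, 0) + 1
    for (src, tgt, sign), count in seen.items():
        if count > 1:
            diagnostics.append(f"duplicate edge {src}->{tgt} (sign {sign:+d}) x{count}")
    for e in graph.edges:
        if e.source == e.target:
            diagnostics.append(f"self-loop on {e.source}")
    for nid, node in graph.nodes.items():
        if not node.genes and not node.is_function:
            diagnostics.append(f"non-gene node {nid}")
    sub = graph.signaling_subgraph()
    effectors = set(find_effectors(graph))
    reaches = set(effectors)
    for eff in effectors:
        reaches |= nx.ancestors(sub, eff)
    for nid in sub.nodes:
        if nid not in reaches:
            diagnostics.append(f"node {nid} unreachable to any effector")
    return diagnostics
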