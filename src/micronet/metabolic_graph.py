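"""Directed metabolite graph of a GEM and its strongly connected components.

Edge semantics follow the standard reverse-ecology construction: every
internal (and, by default, transport) reaction contributes an edge from each
substrate to each product — the complete substrate x product bipartite
expansion — and a reversible reaction contributes both directions.  Exchange
reactions describe boundary flow of a single compound and contribute no
edges.  Stoichiometry is ignored throughout: the method is topological.

The SCC decomposition uses Kosaraju's two-pass algorithm (forward DFS
finishing order, then DFS on the transposed graph), implemented iteratively
so deep graphs do not hit the recursion limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

from .gem_io import GEModel


@dataclass
class DirectedGraph:
    """Adjacency-set digraph over metabolite ids.  Self-edges are ignored."""

    _succ: dict[str, set[str]] = field(default_factory=dict)
    _pred: dict[str, set[str]] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return sorted(self._succ)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {(u, v) for u, vs in self._succ.items() for v in vs}

    def __len__(self) -> int:
        return len(self._succ)

    def add_node(self, u: str) -> None:
        self._succ.setdefault(u, set())
        self._pred.setdefault(u, set())

    def add_edge(self, u: str, v: str) -> None:
        if u == v:
            return
        self.add_node(u)
        self.add_node(v)
        self._succ[u].add(v)
        self._pred[v].add(u)

    def successors(self, u: str) -> set[str]:
        return self._succ[u]

    def predecessors(self, u: str) -> set[str]:
        return self._pred[u]

    def remove_nodes(self, nodes: Iterable[str]) -> None:
        for n in set(nodes):
            if n not in self._succ:
                continue
            for v in self._succ.pop(n):
                self._pred[v].discard(n)
            for u in self._pred.pop(n):
                self._succ[u].discard(n)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass
class SCCPartition:
    """SCC decomposition plus its condensation DAG.

    Components are ordered canonically by their smallest contained
    metabolite id, so the partition of a given graph is deterministic.
    """

    components: list[frozenset[str]]
    component_of: dict[str, int]
    dag_edges: set[tuple[int, int]]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.components]


def build_metabolite_graph(
    model: GEModel,
    exclude: Iterable[str] | None = None,
    include_transport_edges: bool = True,
) -> DirectedGraph:
    """Build the directed metabolite graph of a classified model.

    Parameters
    ----------
    exclude
        Optional currency-metabolite ids (e.g. h2o_c, atp_c) to delete,
        together with their incident edges.  Off by default: removing hub
        cofactors materially changes SCC structure, so it must be explicit.
    include_transport_edges
        When False, transport reactions contribute no edges (cytosolic
        conversions only).
    """
    graph = DirectedGraph()
    excluded = {e.lower() for e in (exclude or ())}
    for rxn in model.reactions.values():
        if rxn.kind == "exchange":
            continue
        if rxn.kind == "transport" and not include_transport_edges:
            continue
        for m in rxn.participants:
            if m not in excluded:
                graph.add_node(m)
        for s in rxn.substrates:
            if s in excluded:
                continue
            for p in rxn.products:
                if p in excluded:
                    continue
                graph.add_edge(s, p)
                if rxn.reversible:
                    graph.add_edge(p, s)
    return graph


def load_currency_list(path: str | Path) -> list[str]:
    """Read a currency-metabolite exclusion list: one id per line, '#' comments."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip().lower()
        if line:
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# Kosaraju


def _dfs_finish_order(graph: DirectedGraph) -> list[str]:
    """Iterative DFS over all nodes (sorted roots/neighbours), returning
    nodes in increasing finishing time."""
    visited: set[str] = set()
    order: list[str] = []
    for root in graph.nodes:
        if root in visited:
            continue
        stack: list[tuple[str, Iterable[str]]] = [(root, iter(sorted(graph.successors(root))))]
        visited.add(root)
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in visited:
                    visited.add(nxt)
                    stack.append((nxt, iter(sorted(graph.successors(nxt)))))
                    advanced = True
                    break
            if not advanced:
                order.append(node)
                stack.pop()
    return order


def kosaraju_scc(graph: DirectedGraph) -> SCCPartition:
    """Decompose a digraph into strongly connected components.

    Pass 1 computes DFS finishing times on the graph; pass 2 runs DFS on
    the transposed graph in decreasing finishing time, each tree being one
    SCC.  The returned components are re-ordered by smallest member id.
    """
    order = _dfs_finish_order(graph)
    assigned: set[str] = set()
    raw_components: list[set[str]] = []
    for root in reversed(order):
        if root in assigned:
            continue
        comp: set[str] = set()
        stack = [root]
        assigned.add(root)
        while stack:
            node = stack.pop()
            comp.add(node)
            for nxt in graph.predecessors(node):  # transposed edges
                if nxt not in assigned:
                    assigned.add(nxt)
                    stack.append(nxt)
        raw_components.append(comp)

    components = sorted((frozenset(c) for c in raw_components), key=min)
    component_of = {n: i for i, comp in enumerate(components) for n in comp}
    dag_edges = {
        (component_of[u], component_of[v])
        for (u, v) in graph.edges
        if component_of[u] != component_of[v]
    }
    return SCCPartition(components=components, component_of=component_of, dag_edges=dag_edges)


def condensation_sources(partition: SCCPartition) -> set[int]:
    """Components with no incoming condensation edge and at least one
    outgoing one — the candidate seed components."""
    has_in = {v for (_, v) in partition.dag_edges}
    has_out = {u for (u, _) in partition.dag_edges}
    return {i for i in range(len(partition.components)) if i not in has_in and i in has_out}


# ---------------------------------------------------------------------------
# export


def write_edgelist(graph: DirectedGraph, path: str | Path) -> None:
    lines = ["source\ttarget"]
    lines += [f"{u}\t{v}" for (u, v) in sorted(graph.edges)]
    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(graph: DirectedGraph, path: str | Path) -> None:
    nx.write_graphml(graph.to_networkx(), str(path))


def condensation_to_networkx(partition: SCCPartition) -> nx.DiGraph:
    g = nx.DiGraph()
    for i, comp in enumerate(partition.components):
        g.add_node(i, members=",".join(sorted(comp)), size=len(comp))
    g.add_edges_from(sorted(partition.dag_edges))
    return g
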