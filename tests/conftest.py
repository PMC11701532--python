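"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the code paths they check:
``scc_oracle`` groups mutually reachable nodes by brute-force BFS, and
``random_digraph`` builds test graphs directly.
"""

from __future__ import annotations

import numpy as np
import pytest

from micronet.metabolic_graph import DirectedGraph


def bfs_reachable(graph: DirectedGraph, start: str) -> set[str]:
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in graph.successors(u):
                if v not in seen:
                    seen.add(v)
                    nxt.append(v)
        frontier = nxt
    return seen


def scc_oracle(graph: DirectedGraph) -> set[frozenset[str]]:
    """Brute-force SCCs: group nodes by mutual pairwise reachability."""
    reach = {n: bfs_reachable(graph, n) for n in graph.nodes}
    comps = set()
    for n in graph.nodes:
        comps.add(frozenset(m for m in graph.nodes if m in reach[n] and n in reach[m]))
    return comps


def random_digraph(n: int, p: float, seed: int) -> DirectedGraph:
    rng = np.random.default_rng(seed)
    g = DirectedGraph()
    names = [f"m{i}" for i in range(n)]
    for name in names:
        g.add_node(name)
    for i in range(n):
        for j in range(n):
            if i != j and rng.random() < p:
                g.add_edge(names[i], names[j])
    return g


def graph_from_edges(edges: list[tuple[str, str]], extra_nodes: list[str] = ()) -> DirectedGraph:
    g = DirectedGraph()
    for n in extra_nodes:
        g.add_node(n)
    for u, v in edges:
        g.add_edge(u, v)
    return g


@pytest.fixture()
def toy3_table(tmp_path):
    """The 3-metabolite chain a_c -> b_c -> c_c as a reaction table file."""
    path = tmp_path / "toy3.tsv"
    path.write_text("rxn_id\tequation\nr1\ta_c -> b_c\nr2\tb_c -> c_c\n")
    return path


@pytest.fixture()
def toy3_sbml(tmp_path):
    """The same chain written as SBML by the fixtures module."""
    from micronet.gem_io import read_reaction_table, write_sbml

    table = tmp_path / "toy3.tsv"
    table.write_text("rxn_id\tequation\nr1\ta_c -> b_c\nr2\tb_c -> c_c\n")
    model = read_reaction_table(table, model_id="toy3")
    path = tmp_path / "toy3.xml"
    write_sbml(model, path)
    return path


@pytest.fixture()
def community(tmp_path):
    from micronet.fixtures import simulate_community

    return simulate_community(tmp_path / "community", n_models=5, rng_seed=11)
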