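"""Independent oracles used across the test suite.

These deliberately avoid the package's production code paths: the
exhaustive-labeling search and the cycle-balance check are alternative
decision procedures for potential-definability, and the pairwise
common-successor count is an alternative Bi-fan counter.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx


def exhaustive_definable(g: nx.DiGraph, levels: int = 8) -> bool:
    """Search all integer labelings in {0..levels-1}^nodes for consistency.

    Depth-first over nodes in undirected-BFS order with immediate
    constraint checking (prunes the same labeling space a full product
    enumeration would visit).  For graphs of at most ``levels`` nodes the
    bounded range is exhaustive: any consistent assignment spans at most
    n-1 units and can be translated into the window.
    """
    und = nx.Graph()
    und.add_nodes_from(g.nodes)
    und.add_edges_from(g.edges())
    order: list = []
    for comp in nx.connected_components(und):
        start = min(comp, key=str)
        order.extend(nx.bfs_tree(und, start).nodes)

    assign: dict = {}

    def consistent(v, val) -> bool:
        for u in g.successors(v):
            if u in assign and assign[u] != val - 1:
                return False
        for u in g.predecessors(v):
            if u in assign and assign[u] != val + 1:
                return False
        return True

    def backtrack(i: int) -> bool:
        if i == len(order):
            return True
        v = order[i]
        for val in range(levels):
            if consistent(v, val):
                assign[v] = val
                if backtrack(i + 1):
                    return True
                del assign[v]
        return False

    return backtrack(0)


def cycle_balance_definable(g: nx.DiGraph) -> bool:
    """Definable iff no reciprocal pair and every undirected basis cycle
    traverses equal numbers of forward and backward arcs."""
    for u, v in g.edges():
        if g.has_edge(v, u):
            return False
    und = nx.Graph(g.edges())
    for cycle in nx.cycle_basis(und):
        total = 0
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            total += -1 if g.has_edge(a, b) else +1
        if total != 0:
            return False
    return True


def count_bifans_pairwise(g: nx.DiGraph) -> int:
    """Bi-fan count via common out-neighbors of source pairs."""
    nodes = list(g.nodes)
    total = 0
    for u1, u2 in itertools.combinations(nodes, 2):
        shared = len(set(g.successors(u1)) & set(g.successors(u2)))
        total += math.comb(shared, 2)
    return total


def closed_walk_checks(g: nx.DiGraph, witness) -> None:
    """Assert a conflict witness is a genuine certificate."""
    assert witness.imbalance != 0
    seq = []
    for (a, b), s in zip(witness.steps, witness.signs):
        assert g.has_edge(a, b), f"witness step {(a, b)} is not an arc of g"
        seq.append((a, b) if s == -1 else (b, a))
    for (_, end), (start, _) in zip(seq, seq[1:]):
        assert end == start, "witness steps do not chain into a walk"
    assert seq[-1][1] == seq[0][0], "witness walk is not closed"
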