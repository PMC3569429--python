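"""Integer node potentials under the unit-drop rule.

A directed graph is *potential-definable* when every node can be given an
integer potential such that each arc runs from a node whose potential is
exactly one unit higher to one exactly one unit lower.  A single arc is
definable; any reciprocal pair is not; feed-forward loops are acyclic yet
still not definable.  Definability captures a strict local hierarchy: the
potential of a node is its level.

The assignment is found by breadth-first labelling over the *underlying
undirected* graph: traversing an arc forward steps the potential down by
one, traversing it backward steps it up by one.  A conflict is certified
by a closed walk whose signed unit steps do not sum to zero.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Hashable

import networkx as nx

Arc = tuple[Hashable, Hashable]

__all__ = [
    "ConflictWitness",
    "PotentialAssignment",
    "assign_potentials",
    "is_potential_definable",
    "potential_level_count",
]


@dataclass(frozen=True)
class ConflictWitness:
    """Certificate of non-definability: a closed walk with nonzero drop.

    ``steps`` lists arcs of the graph in traversal order; ``signs[i]`` is
    -1 when ``steps[i]`` is traversed forward (a unit drop) and +1 when
    traversed backward.  Under the unit-drop rule the potential change
    around a closed walk must vanish, so ``sum(signs) != 0`` proves no
    consistent assignment exists.
    """

    steps: tuple[Arc, ...]
    signs: tuple[int, ...]

    @property
    def imbalance(self) -> int:
        return sum(self.signs)


@dataclass(frozen=True)
class PotentialAssignment:
    definable: bool
    potentials: dict[Hashable, int] | None = None
    witness: ConflictWitness | None = None


def _tree_path(parents: dict, a: Hashable, b: Hashable) -> list[Hashable]:
    """Node path from a to b through the BFS forest (same component)."""
    anc_a = [a]
    while parents[anc_a[-1]] is not None:
        anc_a.append(parents[anc_a[-1]])
    index = {n: i for i, n in enumerate(anc_a)}
    path_b = [b]
    while path_b[-1] not in index:
        path_b.append(parents[path_b[-1]])
    meet = path_b[-1]
    return anc_a[: index[meet] + 1] + path_b[-2::-1]


def _witness(g: nx.DiGraph, parents: dict, src: Hashable, dst: Hashable) -> ConflictWitness:
    # Closed walk: tree path dst -> src, then the conflicting arc src -> dst.
    steps: list[Arc] = []
    signs: list[int] = []
    path = _tree_path(parents, dst, src)
    for a, b in zip(path, path[1:]):
        if g.has_edge(a, b):
            steps.append((a, b))
            signs.append(-1)
        else:
            steps.append((b, a))
            signs.append(+1)
    steps.append((src, dst))
    signs.append(-1)
    return ConflictWitness(tuple(steps), tuple(signs))


def assign_potentials(g: nx.DiGraph) -> PotentialAssignment:
    """BFS labelling of node potentials; linear in nodes plus arcs.

    Each weakly connected component is labelled independently and
    normalized so its minimum potential is 0 (the rule only fixes
    differences, so a canonical representative keeps output reproducible).
    Disconnected graphs are definable iff every component is.

    Raises
    ------
    ValueError
        If the graph contains a self-loop (no finite potential step fits).
    """
    for u, v in nx.selfloop_edges(g):
        raise ValueError(f"self-loop on node {u!r}: potentials are undefined")

    pot: dict[Hashable, int] = {}
    parents: dict[Hashable, Hashable | None] = {}
    components: list[list[Hashable]] = []
    seen: set[Hashable] = set()
    for start in sorted(g.nodes, key=str):
        if start in seen:
            continue
        comp = [start]
        pot[start] = 0
        parents[start] = None
        seen.add(start)
        queue = deque([start])
        while queue:
            u = queue.popleft()
            # reciprocal pair: immediate two-step conflict
            for v in g.successors(u):
                if g.has_edge(v, u):
                    return PotentialAssignment(
                        definable=False,
                        witness=ConflictWitness(((u, v), (v, u)), (-1, -1)),
                    )
            neighbors = [(v, -1) for v in g.successors(u)] + [
                (v, +1) for v in g.predecessors(u)
            ]
            for v, step in neighbors:
                if v not in seen:
                    seen.add(v)
                    pot[v] = pot[u] + step
                    parents[v] = u
                    comp.append(v)
                    queue.append(v)
                elif pot[v] != pot[u] + step:
                    src, dst = (u, v) if step == -1 else (v, u)
                    return PotentialAssignment(
                        definable=False, witness=_witness(g, parents, src, dst)
                    )
        components.append(comp)

    for comp in components:
        lo = min(pot[n] for n in comp)
        for n in comp:
            pot[n] -= lo
    return PotentialAssignment(definable=True, potentials=pot)


def is_potential_definable(g: nx.DiGraph) -> bool:
    """Whether the unit-drop rule admits a consistent integer labelling."""
    return assign_potentials(g).definable


def potential_level_count(a: PotentialAssignment) -> int:
    """Number of distinct potential levels of a definable assignment.

    Fewer levels means a more homogeneous structure (the Bi-fan has two,
    the Bi-parallel three).
    """
    if not a.definable:
        raise ValueError("potential levels are undefined for a non-definable graph")
    assert a.potentials is not None
    return len(set(a.potentials.values())) if a.potentials else 0
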