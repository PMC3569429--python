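"""Minimal loop-embedded subgraphs of orders 3-4 and the twelve predictors.

A *loop-embedded* digraph contains a cycle in its underlying undirected
graph; reciprocal arc pairs do not count as loops and are barred from
patterns altogether.  Subgraphs here are *generalized*: any node subset
together with any subset of the arcs among them, not only induced
subgraphs.  A pattern is *minimal* loop-embedded when no proper
generalized subgraph of it is itself loop-embedded — which forces the
undirected skeleton to be a single cycle through every node.

Brute-force enumeration over all reciprocal-free digraphs on 3 or 4
labelled nodes yields exactly six isomorphism classes:

======  =====  ====================================  ==========
name    order  role arcs                             definable
======  =====  ====================================  ==========
3-FFL     3    0>1, 1>2, 0>2                         no
3-Loop    3    0>1, 1>2, 2>0                         no
Bi-fan    4    0>2, 0>3, 1>2, 1>3                    yes (2 levels)
Bi-par.   4    0>1, 0>2, 1>3, 2>3                    yes (3 levels)
4-Loop    4    0>1, 1>2, 2>3, 3>0                    no
4-FFL     4    0>1, 1>2, 2>3, 0>3                    no
======  =====  ====================================  ==========

Removing one arc per automorphism orbit from each pattern yields the
twelve link predictors S1..S12, grouped per parent as
3-FFL:{S1,S2,S3}, 3-Loop:{S4}, Bi-fan:{S5}, Bi-parallel:{S6,S7},
4-Loop:{S8}, 4-FFL:{S9..S12}.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import networkx as nx

RoleArc = tuple[int, int]

__all__ = [
    "PatternGraph",
    "PredictorSpec",
    "CATALOG_NAMES",
    "enumerate_minimal_loop_embedded",
    "get_catalog",
    "get_pattern",
    "classify_pattern",
    "link_orbits",
    "derive_predictors",
    "predictor_by_id",
    "predictor_group",
]

#: Catalog order fixes the S1..S12 labelling.
CATALOG_NAMES = ("3-FFL", "3-Loop", "Bi-fan", "Bi-parallel", "4-Loop", "4-FFL")

_ROLE_ARCS: dict[str, frozenset[RoleArc]] = {
    "3-FFL": frozenset({(0, 1), (1, 2), (0, 2)}),
    "3-Loop": frozenset({(0, 1), (1, 2), (2, 0)}),
    "Bi-fan": frozenset({(0, 2), (0, 3), (1, 2), (1, 3)}),
    "Bi-parallel": frozenset({(0, 1), (0, 2), (1, 3), (2, 3)}),
    "4-Loop": frozenset({(0, 1), (1, 2), (2, 3), (3, 0)}),
    "4-FFL": frozenset({(0, 1), (1, 2), (2, 3), (0, 3)}),
}


def _automorphisms(order: int, arcs: frozenset[RoleArc]) -> tuple[tuple[int, ...], ...]:
    auts = []
    for perm in itertools.permutations(range(order)):
        if frozenset((perm[a], perm[b]) for a, b in arcs) == arcs:
            auts.append(perm)
    return tuple(auts)


def _canonical_form(order: int, arcs: frozenset[RoleArc]) -> tuple[RoleArc, ...]:
    """Minimum relabelled arc tuple over all node permutations.

    At order <= 4 this is at most 24 permutations; cheap and deterministic.
    """
    return min(
        tuple(sorted((perm[a], perm[b]) for a, b in arcs))
        for perm in itertools.permutations(range(order))
    )


@dataclass(frozen=True)
class PatternGraph:
    """A small directed pattern with its automorphism group on role indices."""

    name: str
    order: int
    arcs: frozenset[RoleArc]
    automorphisms: tuple[tuple[int, ...], ...] = field(compare=False)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.order))
        g.add_edges_from(self.arcs)
        return g


@dataclass(frozen=True)
class PredictorSpec:
    """One predictor: a parent pattern with a distinguished removed arc.

    A candidate link's score is the number of parent occurrences its
    addition completes with the candidate in the ``probe_arc`` role.
    """

    id: str
    parent: PatternGraph
    probe_arc: RoleArc

    @property
    def residual_arcs(self) -> frozenset[RoleArc]:
        return self.parent.arcs - {self.probe_arc}


def _make_pattern(name: str) -> PatternGraph:
    arcs = _ROLE_ARCS[name]
    order = 3 if name.startswith("3") else 4
    return PatternGraph(name, order, arcs, _automorphisms(order, arcs))


@lru_cache(maxsize=1)
def get_catalog() -> tuple[PatternGraph, ...]:
    """The six catalog patterns, in canonical (S-labelling) order."""
    return tuple(_make_pattern(name) for name in CATALOG_NAMES)


def get_pattern(name: str) -> PatternGraph:
    for p in get_catalog():
        if p.name.lower() == name.lower():
            return p
    raise KeyError(f"unknown pattern {name!r}; expected one of {CATALOG_NAMES}")


def _is_loop_embedded(arcs) -> bool:
    # Reciprocal-free, so each arc is a distinct undirected edge; detect an
    # undirected cycle by union-find.
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in arcs:
        ra, rb = find(a), find(b)
        if ra == rb:
            return True
        parent[ra] = rb
    return False


def _is_minimal(order: int, arcs: frozenset[RoleArc]) -> bool:
    # Loop-embeddedness is monotone in (nodes, arcs), so it suffices to
    # check the maximal proper generalized subgraphs: drop one arc, or
    # drop one node with its incident arcs.
    for e in arcs:
        if _is_loop_embedded(arcs - {e}):
            return False
    for v in range(order):
        if _is_loop_embedded([a for a in arcs if v not in a]):
            return False
    return True


def _is_minimal_exhaustive(order: int, arcs: frozenset[RoleArc]) -> bool:
    """Direct minimality re-check over every proper generalized subgraph."""
    def powerset(seq):
        seq = sorted(seq)
        return itertools.chain.from_iterable(
            itertools.combinations(seq, r) for r in range(len(seq) + 1)
        )

    nodes = frozenset(range(order))
    for node_sub in map(frozenset, powerset(nodes)):
        inner = [a for a in arcs if a[0] in node_sub and a[1] in node_sub]
        for arc_sub in map(frozenset, powerset(inner)):
            if node_sub == nodes and arc_sub == arcs:
                continue
            if _is_loop_embedded(arc_sub):
                return False
    return True


def enumerate_minimal_loop_embedded(order: int) -> list[PatternGraph]:
    """Brute-force enumeration of minimal loop-embedded patterns.

    Generates every digraph on ``order`` labelled nodes with no self-loop
    and no reciprocal pair (each unordered node pair is empty, forward, or
    backward), keeps the loop-embedded ones whose every proper generalized
    subgraph is loop-free, and deduplicates by canonical form.

    Order 2 is permitted and returns an empty list: its only loop
    candidate is a reciprocal pair, which is excluded by definition.
    """
    if order not in (2, 3, 4):
        raise ValueError(f"order {order} unsupported; catalog covers orders 2-4")
    pairs = list(itertools.combinations(range(order), 2))
    found: dict[tuple[RoleArc, ...], frozenset[RoleArc]] = {}
    for choice in itertools.product((None, 0, 1), repeat=len(pairs)):
        arcs = frozenset(
            (a, b) if c == 0 else (b, a)
            for (a, b), c in zip(pairs, choice)
            if c is not None
        )
        if not _is_loop_embedded(arcs):
            continue
        if not _is_minimal(order, arcs):
            continue
        found.setdefault(_canonical_form(order, arcs), arcs)
    patterns = [
        PatternGraph(
            classify_pattern(order, arcs), order, arcs, _automorphisms(order, arcs)
        )
        for arcs in found.values()
    ]
    return sorted(patterns, key=lambda p: CATALOG_NAMES.index(p.name))


@lru_cache(maxsize=1)
def _canonical_index() -> dict[tuple[RoleArc, ...], str]:
    return {
        _canonical_form(p.order, p.arcs): p.name
        for p in (_make_pattern(n) for n in CATALOG_NAMES)
    }


def classify_pattern(order_or_pattern, arcs=None) -> str:
    """Canonical catalog name of a pattern, by isomorphism matching.

    Accepts a :class:`PatternGraph` or an ``(order, arcs)`` pair.

    Raises
    ------
    ValueError
        If the graph is not isomorphic to any catalog member.
    """
    if isinstance(order_or_pattern, PatternGraph):
        order, arcs = order_or_pattern.order, order_or_pattern.arcs
    else:
        order = order_or_pattern
    form = _canonical_form(order, frozenset(arcs))
    try:
        return _canonical_index()[form]
    except KeyError:
        raise ValueError(
            f"graph on {order} nodes with arcs {sorted(arcs)} is not a "
            "minimal loop-embedded catalog pattern"
        ) from None


def link_orbits(p: PatternGraph) -> list[RoleArc]:
    """One representative arc per automorphism orbit, in canonical order.

    Two removed arcs related by a pattern automorphism give the same
    predictor, so predictors are in bijection with arc orbits.
    """
    remaining = set(p.arcs)
    reps: list[RoleArc] = []
    while remaining:
        rep = min(remaining)
        orbit = {(perm[rep[0]], perm[rep[1]]) for perm in p.automorphisms}
        remaining -= orbit
        reps.append(rep)
    return sorted(reps)


@lru_cache(maxsize=1)
def derive_predictors() -> tuple[PredictorSpec, ...]:
    """The twelve predictors S1..S12, one per (pattern, arc-orbit).

    The orbit representative within each parent follows the canonical arc
    order of :func:`link_orbits`; any consistent choice gives equivalent
    predictors because occurrences are counted modulo automorphisms.

    The automorphism subgroup fixing each probe arc must be trivial (so
    occurrence counting reduces to counting role assignments of the free
    nodes); this is asserted at build time.
    """
    specs: list[PredictorSpec] = []
    k = 1
    for p in get_catalog():
        for probe in link_orbits(p):
            stab = [
                perm
                for perm in p.automorphisms
                if perm[probe[0]] == probe[0] and perm[probe[1]] == probe[1]
            ]
            assert len(stab) == 1, f"nontrivial probe-arc stabilizer in {p.name}"
            specs.append(PredictorSpec(f"S{k}", p, probe))
            k += 1
    assert len(specs) == 12
    return tuple(specs)


def predictor_by_id(pid: str) -> PredictorSpec:
    for s in derive_predictors():
        if s.id.lower() == pid.lower():
            return s
    raise KeyError(f"unknown predictor id {pid!r}; expected S1..S12")


def predictor_group(parent_name: str) -> tuple[PredictorSpec, ...]:
    """All predictors sharing one parent pattern (a hybrid grouping)."""
    name = get_pattern(parent_name).name
    return tuple(s for s in derive_predictors() if s.parent.name == name)
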