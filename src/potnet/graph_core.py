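"""Directed-graph loading, normalization, and structural summaries.

The package works on simple directed graphs: no self-loops, no duplicate
arcs, reciprocal arc pairs allowed.  Graphs are held as
:class:`networkx.DiGraph`; node identifiers are opaque (strings from the
file readers, anything hashable from the generators).

All readers normalize on the way in: duplicate arcs collapse, self-loops
are dropped with a logged warning, and any weights or extra tokens are
ignored — the analysis in this package is purely topological.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from typing import Hashable, Iterable

import networkx as nx

logger = logging.getLogger(__name__)

Arc = tuple[Hashable, Hashable]

__all__ = [
    "GraphFormatError",
    "StructuralSummary",
    "build_digraph",
    "read_edgelist",
    "write_edgelist",
    "read_pajek",
    "largest_weakly_connected_component",
    "structural_summary",
]


class GraphFormatError(ValueError):
    """Raised for malformed or out-of-contract graph input."""


def build_digraph(arcs: Iterable[Arc], nodes: Iterable[Hashable] = ()) -> nx.DiGraph:
    """Build a normalized simple digraph from an arc iterable.

    Duplicate arcs collapse (set semantics); self-loops are dropped with a
    warning.  ``nodes`` adds isolated nodes beyond arc endpoints.
    """
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    n_self = 0
    for u, v in arcs:
        if u == v:
            n_self += 1
            g.add_node(u)
            continue
        g.add_edge(u, v)
    if n_self:
        logger.warning("dropped %d self-loop(s) during normalization", n_self)
    return g


def read_edgelist(path, comment_prefix: str = "#") -> nx.DiGraph:
    """Read a directed edge list: one ``source target`` arc per line.

    Extra whitespace-separated tokens (e.g. weights) are ignored.  Lines
    starting with ``comment_prefix`` and blank lines are skipped.

    Raises
    ------
    GraphFormatError
        If a non-comment line has fewer than two tokens (the message names
        the 1-based line number), or if the file yields an empty graph.
    """
    arcs: list[Arc] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise GraphFormatError(
                    f"{path}: line {lineno}: expected 'source target', got {line!r}"
                )
            arcs.append((tokens[0], tokens[1]))
    if not arcs:
        raise GraphFormatError(f"{path}: no arcs found (empty graph)")
    return build_digraph(arcs)


def write_edgelist(g: nx.DiGraph, path) -> None:
    """Write one ``source target`` line per arc, sorted for determinism."""
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(g.edges(), key=lambda a: (str(a[0]), str(a[1]))):
            fh.write(f"{u} {v}\n")


def read_pajek(path) -> nx.DiGraph:
    """Read the Pajek ``.net`` subset: *Vertices, *Arcs, *Edges.

    ``*Arcs`` lines become single directed arcs; ``*Edges`` lines expand to
    reciprocal arc pairs (an undirected line in a directed container has no
    other faithful reading).  Vertex numbering is 1-based; quoted labels
    are preserved as node identifiers, otherwise the index string is used.
    All declared vertices are kept, including isolated ones.
    """
    n_vertices = None
    labels: dict[int, str] = {}
    arcs: list[tuple[int, int, bool]] = []  # (src, dst, reciprocal)
    section = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*"):
                if low.startswith("*vertices"):
                    parts = line.split()
                    if len(parts) < 2 or not parts[1].isdigit():
                        raise GraphFormatError(
                            f"{path}: line {lineno}: malformed *Vertices header"
                        )
                    n_vertices = int(parts[1])
                    section = "vertices"
                elif low.startswith("*arcs"):
                    section = "arcs"
                elif low.startswith("*edges"):
                    section = "edges"
                else:
                    section = "other"
                continue
            if section == "vertices":
                parts = line.split(None, 1)
                idx = int(parts[0])
                if len(parts) > 1:
                    labels[idx] = parts[1].strip().strip('"')
            elif section in ("arcs", "edges"):
                if n_vertices is None:
                    raise GraphFormatError(
                        f"{path}: line {lineno}: arc data before *Vertices"
                    )
                parts = line.split()
                if len(parts) < 2:
                    raise GraphFormatError(
                        f"{path}: line {lineno}: expected two vertex indices"
                    )
                try:
                    i, j = int(parts[0]), int(parts[1])
                except ValueError as exc:
                    raise GraphFormatError(
                        f"{path}: line {lineno}: non-integer vertex index"
                    ) from exc
                if not (1 <= i <= n_vertices and 1 <= j <= n_vertices):
                    raise GraphFormatError(
                        f"{path}: line {lineno}: vertex index out of range "
                        f"1..{n_vertices}"
                    )
                arcs.append((i, j, section == "edges"))
    if n_vertices is None:
        raise GraphFormatError(f"{path}: missing *Vertices section")

    def name(i: int) -> str:
        return labels.get(i, str(i))

    directed: list[Arc] = []
    for i, j, reciprocal in arcs:
        directed.append((name(i), name(j)))
        if reciprocal:
            directed.append((name(j), name(i)))
    return build_digraph(directed, nodes=(name(i) for i in range(1, n_vertices + 1)))


def largest_weakly_connected_component(g: nx.DiGraph) -> nx.DiGraph:
    """Node-induced subgraph on the largest weakly connected component.

    Ties in component size are broken toward the component containing the
    lexicographically smallest node label, so output is deterministic.
    """
    if g.number_of_nodes() == 0:
        raise GraphFormatError("cannot extract component of an empty graph")
    best = min(
        nx.weakly_connected_components(g),
        key=lambda c: (-len(c), min(str(n) for n in c)),
    )
    return g.subgraph(best).copy()


@dataclass(frozen=True)
class StructuralSummary:
    """Basic structural features of a weakly connected digraph.

    ``avg_degree`` is arcs per node (average in-degree equals average
    out-degree).  ``effective_diameter_90`` is the linearly interpolated
    90th percentile of finite ordered-pair shortest-path hop counts.
    ``directed_clustering`` averages Fagiolo's directed clustering
    coefficient over all nodes, with nodes of total degree below 2
    contributing 0.
    """

    n_nodes: int
    n_arcs: int
    max_in_degree: int
    max_out_degree: int
    avg_degree: float
    effective_diameter_90: float
    directed_clustering: float

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        rows = [
            ("nodes (N)", self.n_nodes),
            ("arcs (M)", self.n_arcs),
            ("max in-degree", self.max_in_degree),
            ("max out-degree", self.max_out_degree),
            ("average degree", f"{self.avg_degree:.4g}"),
            ("90% effective diameter", f"{self.effective_diameter_90:.4g}"),
            ("directed clustering", f"{self.directed_clustering:.4g}"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def _effective_diameter_90(g: nx.DiGraph) -> float:
    # Exact all-pairs BFS; fine at the scales this package targets.
    counts: dict[int, int] = {}
    for _, dists in nx.all_pairs_shortest_path_length(g):
        for d in dists.values():
            if d > 0:
                counts[d] = counts.get(d, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0
    cum = 0
    prev_frac = 0.0
    for d in sorted(counts):
        cum += counts[d]
        frac = cum / total
        if frac >= 0.9:
            return (d - 1) + (0.9 - prev_frac) / (frac - prev_frac)
        prev_frac = frac
    return float(max(counts))  # unreachable; guards rounding pathologies


def structural_summary(g: nx.DiGraph) -> StructuralSummary:
    """Compute the structural feature set for one weakly connected graph.

    Raises
    ------
    GraphFormatError
        If the graph is empty or not weakly connected (extract the largest
        weakly connected component first).
    """
    if g.number_of_nodes() == 0:
        raise GraphFormatError("empty graph")
    if not nx.is_weakly_connected(g):
        raise GraphFormatError(
            "graph is not weakly connected; apply "
            "largest_weakly_connected_component first"
        )
    n = g.number_of_nodes()
    m = g.number_of_edges()
    # nx.clustering on a DiGraph implements Fagiolo's directed coefficient;
    # degree-<2 nodes come back as 0, matching the convention used here.
    clustering = nx.clustering(g)
    return StructuralSummary(
        n_nodes=n,
        n_arcs=m,
        max_in_degree=max(d for _, d in g.in_degree()),
        max_out_degree=max(d for _, d in g.out_degree()),
        avg_degree=m / n,
        effective_diameter_90=_effective_diameter_90(g),
        directed_clustering=float(sum(clustering.values()) / n) if n else 0.0,
    )
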