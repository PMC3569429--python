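"""Seeded synthetic directed networks and named small fixtures.

Everything here is bit-reproducible from a seed.  The generators emulate
the regimes the method targets: sparse directed graphs at food-web scale
(tens to hundreds of nodes, average degree around 3-15), layered DAGs
whose every arc drops exactly one level (potential-definable by
construction), and bipartite source->sink graphs planted with Bi-fan
structure.  Generated node identifiers are integers; fixtures use
lowercase letters in documented role order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .catalog import CATALOG_NAMES, get_pattern
from .graph_core import build_digraph

__all__ = [
    "GeneratorConfig",
    "random_digraph",
    "layered_dag",
    "planted_bifan_graph",
    "expected_bifan_count",
    "fixture",
    "FIXTURE_NAMES",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Density is set by exactly one of ``n_arcs`` (exact count, sampled
    without replacement) or ``arc_probability`` (independent inclusion)."""

    n_nodes: int
    n_arcs: int | None = None
    arc_probability: float | None = None
    allow_reciprocal: bool = True
    layers: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if (self.n_arcs is None) == (self.arc_probability is None):
            raise ValueError("set exactly one of n_arcs or arc_probability")
        if self.arc_probability is not None and not 0 <= self.arc_probability <= 1:
            raise ValueError("arc_probability must lie in [0, 1]")


def _sample_exact(pairs: list, m: int, rng: np.random.Generator) -> list:
    if m > len(pairs):
        raise ValueError(
            f"requested {m} arcs but only {len(pairs)} positions are available"
        )
    idx = rng.choice(len(pairs), size=m, replace=False)
    return [pairs[i] for i in idx]


def random_digraph(cfg: GeneratorConfig) -> nx.DiGraph:
    """Uniform simple digraph at the requested density; no self-loops.

    With ``allow_reciprocal=False`` arcs are drawn as undirected pairs and
    then oriented at random, so the feasible count halves and every
    output is reciprocal-free (such graphs always fail definability as
    soon as any 2-cycle would appear, which this mode forbids).
    """
    n = cfg.n_nodes
    rng = np.random.default_rng(cfg.seed)
    if cfg.allow_reciprocal:
        pairs = [(u, v) for u in range(n) for v in range(n) if u != v]
        if cfg.n_arcs is not None:
            arcs = _sample_exact(pairs, cfg.n_arcs, rng)
        else:
            keep = rng.random(len(pairs)) < cfg.arc_probability
            arcs = [p for p, k in zip(pairs, keep) if k]
    else:
        und = list(itertools.combinations(range(n), 2))
        if cfg.n_arcs is not None:
            chosen = _sample_exact(und, cfg.n_arcs, rng)
        else:
            keep = rng.random(len(und)) < cfg.arc_probability
            chosen = [p for p, k in zip(und, keep) if k]
        flips = rng.integers(0, 2, size=len(chosen))
        arcs = [(b, a) if f else (a, b) for (a, b), f in zip(chosen, flips)]
    return build_digraph(arcs, nodes=range(n))


def layered_dag(cfg: GeneratorConfig) -> nx.DiGraph:
    """Layered DAG: arcs run only from layer l+1 down to layer l.

    Nodes are split as evenly as possible across ``cfg.layers`` layers;
    every arc drops exactly one level, so the output is always
    potential-definable and (within each weakly connected component)
    recovers the layer indices up to translation.  Layer membership is
    recorded in the node attribute ``"layer"``.
    """
    if cfg.layers is None or cfg.layers < 2:
        raise ValueError("layered mode needs layers >= 2")
    n, n_layers = cfg.n_nodes, cfg.layers
    if n < n_layers:
        raise ValueError("need at least one node per layer")
    base, extra = divmod(n, n_layers)
    layers: list[list[int]] = []
    node = 0
    for i in range(n_layers):
        size = base + (1 if i < extra else 0)
        layers.append(list(range(node, node + size)))
        node += size
    allowed = [
        (u, v)
        for i in range(n_layers - 1)
        for u in layers[i + 1]
        for v in layers[i]
    ]
    rng = np.random.default_rng(cfg.seed)
    if cfg.n_arcs is not None:
        arcs = _sample_exact(allowed, cfg.n_arcs, rng)
    else:
        keep = rng.random(len(allowed)) < cfg.arc_probability
        arcs = [p for p, k in zip(allowed, keep) if k]
    g = build_digraph(arcs, nodes=range(n))
    for i, members in enumerate(layers):
        for u in members:
            g.nodes[u]["layer"] = i
    return g


def expected_bifan_count(sources: int, sinks: int, p: float) -> float:
    """Closed-form expected Bi-fan count: C(S,2) * C(T,2) * p^4."""
    return math.comb(sources, 2) * math.comb(sinks, 2) * p**4


def planted_bifan_graph(
    sources: int, sinks: int, arc_probability: float, seed: int = 0
) -> nx.DiGraph:
    """Bipartite source->sink digraph with independent arc inclusion.

    Acyclic by construction (all arcs one way across the bipartition);
    rich in Bi-fans and devoid of directed triangles, so 3-Loop-based
    scores are identically zero on it.  The closed-form expected Bi-fan
    count is stored in ``g.graph["expected_bifan_count"]``.
    """
    if sources < 2 or sinks < 2:
        raise ValueError("need at least 2 sources and 2 sinks")
    if not 0 < arc_probability <= 1:
        raise ValueError("arc_probability must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    src = [f"s{i}" for i in range(sources)]
    dst = [f"t{j}" for j in range(sinks)]
    keep = rng.random((sources, sinks)) < arc_probability
    arcs = [
        (src[i], dst[j]) for i in range(sources) for j in range(sinks) if keep[i, j]
    ]
    g = build_digraph(arcs, nodes=src + dst)
    g.graph["expected_bifan_count"] = expected_bifan_count(
        sources, sinks, arc_probability
    )
    return g


def _letters(k: int) -> list[str]:
    if k > 26:
        raise ValueError("letter fixtures support at most 26 nodes")
    return [chr(ord("a") + i) for i in range(k)]


def _pattern_fixture(name: str) -> nx.DiGraph:
    p = get_pattern(name)
    lab = _letters(p.order)
    return build_digraph(((lab[a], lab[b]) for a, b in sorted(p.arcs)), nodes=lab)


FIXTURE_NAMES = (
    "path_<k>",
    "directed_cycle_<k>",
    "reciprocal_pair",
    "ffl",
    *[n.lower() for n in CATALOG_NAMES],
)


def fixture(name: str) -> nx.DiGraph:
    """Named small graphs with documented lowercase-letter node labels.

    ``path_k`` is the directed path a->b->...->  (k arcs, k+1 nodes);
    ``directed_cycle_k`` the directed k-cycle; ``ffl`` is an alias for the
    3-FFL; the six catalog patterns are addressable by (case-insensitive)
    name with roles mapped to a, b, c, d in role-index order.
    """
    key = name.lower()
    if key.startswith("path_"):
        k = int(key.removeprefix("path_"))
        lab = _letters(k + 1)
        return build_digraph(zip(lab, lab[1:]), nodes=lab)
    if key.startswith("directed_cycle_"):
        k = int(key.removeprefix("directed_cycle_"))
        if k < 2:
            raise ValueError("directed cycle needs at least 2 nodes")
        lab = _letters(k)
        return build_digraph(zip(lab, lab[1:] + lab[:1]), nodes=lab)
    if key == "reciprocal_pair":
        return build_digraph([("a", "b"), ("b", "a")])
    if key == "ffl":
        key = "3-ffl"
    if key in (n.lower() for n in CATALOG_NAMES):
        return _pattern_fixture(key)
    raise KeyError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )
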