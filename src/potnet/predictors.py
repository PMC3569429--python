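"""Subgraph-completion scores for candidate directed links.

The score of a non-observed link under predictor ``Sk`` is the number of
occurrences of the predictor's parent pattern that the link's addition
creates with the link in the removed-arc (probe) role.  An occurrence is
an injective mapping of pattern roles to distinct graph nodes such that
every pattern arc maps to a present arc; extra arcs among the image nodes
— including a reciprocal partner of the candidate — are ignored, because
subgraphs are generalized (non-induced).  Occurrences are counted modulo
parent automorphisms; every probe arc has a trivial automorphism
stabilizer, so this reduces to counting role assignments of the free
nodes.

:func:`score_link` is the transparent brute-force reference;
:func:`score_link_fast` computes the identical value by neighborhood-set
intersection and is the path used by the evaluation pipeline.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping

import networkx as nx

from .catalog import PatternGraph, PredictorSpec

logger = logging.getLogger(__name__)

Arc = tuple[Hashable, Hashable]

__all__ = [
    "ScoreTable",
    "score_link",
    "score_link_fast",
    "hybrid_score",
    "score_all",
    "count_occurrences",
]


@dataclass(frozen=True)
class ScoreTable:
    predictor_id: str
    scores: Mapping[Arc, int]


def _validate_candidate(train: nx.DiGraph, candidate: Arc) -> None:
    x, y = candidate
    if x == y:
        raise ValueError(f"candidate {candidate!r} is a self-loop")
    if train.has_edge(x, y):
        raise ValueError(f"candidate {candidate!r} is already an observed link")


def score_link(train: nx.DiGraph, candidate: Arc, spec: PredictorSpec) -> int:
    """Brute-force occurrence count (reference implementation).

    Enumerates every injective assignment of the parent's free roles to
    graph nodes with the probe roles pinned to the candidate endpoints,
    then divides by the (trivial) probe-arc stabilizer.
    """
    _validate_candidate(train, candidate)
    x, y = candidate
    ps, pt = spec.probe_arc
    free = [r for r in range(spec.parent.order) if r not in (ps, pt)]
    others = [v for v in train.nodes if v != x and v != y]

    def present(a: Hashable, b: Hashable) -> bool:
        return (a, b) == candidate or train.has_edge(a, b)

    count = 0
    for combo in itertools.permutations(others, len(free)):
        assign = {ps: x, pt: y}
        assign.update(zip(free, combo))
        if all(present(assign[a], assign[b]) for a, b in spec.parent.arcs):
            count += 1
    stab = sum(
        1
        for perm in spec.parent.automorphisms
        if perm[ps] == ps and perm[pt] == pt
    )
    return count // stab


def _role_candidates(
    train: nx.DiGraph, role: int, fixed: dict[int, Hashable], residual
) -> set:
    """Nodes that satisfy all residual arcs between ``role`` and fixed roles."""
    out: set | None = None
    for a, b in residual:
        if a == role and b in fixed:
            s = set(train.predecessors(fixed[b])) if fixed[b] in train else set()
        elif b == role and a in fixed:
            s = set(train.successors(fixed[a])) if fixed[a] in train else set()
        else:
            continue
        out = s if out is None else (out & s)
        if not out:
            return set()
    if out is None:  # cannot happen for catalog patterns (skeleton is a cycle)
        out = set(train.nodes)
    return out - set(fixed.values())


def score_link_fast(train: nx.DiGraph, candidate: Arc, spec: PredictorSpec) -> int:
    """Closed-form neighborhood counting; equals :func:`score_link`.

    With the probe pinned, an order-3 pattern leaves one free role (count
    one intersection of adjacency sets); an order-4 pattern leaves two
    adjacent free roles (sum, over one role's candidates, the matching
    neighbors in the other's candidate set).  Worst-case cost is the
    product of at most two adjacency-list sizes.
    """
    _validate_candidate(train, candidate)
    x, y = candidate
    ps, pt = spec.probe_arc
    fixed = {ps: x, pt: y}
    free = [r for r in range(spec.parent.order) if r not in (ps, pt)]
    residual = spec.residual_arcs

    if len(free) == 1:
        return len(_role_candidates(train, free[0], fixed, residual))

    r1, r2 = free
    set1 = _role_candidates(train, r1, fixed, residual)
    if not set1:
        return 0
    set2 = _role_candidates(train, r2, fixed, residual)
    if not set2:
        return 0
    if (r1, r2) in residual:
        return sum(len((set(train.successors(u)) & set2) - {u}) for u in set1)
    if (r2, r1) in residual:
        return sum(len((set(train.predecessors(u)) & set2) - {u}) for u in set1)
    # no arc between the free roles: any distinct pair
    return len(set1) * len(set2) - len(set1 & set2)


def hybrid_score(
    train: nx.DiGraph, candidate: Arc, specs: Iterable[PredictorSpec]
) -> int:
    """Sum of member scores, e.g. a whole parent grouping.

    Summing a full parent group counts every created occurrence of the
    parent pattern regardless of the candidate's role (the group
    {S1,S2,S3} counts all created 3-FFLs).
    """
    specs = list(specs)
    if not specs:
        raise ValueError("empty predictor set")
    return sum(score_link_fast(train, candidate, s) for s in specs)


def score_all(
    train: nx.DiGraph,
    candidates: Iterable[Arc],
    spec_or_specs: PredictorSpec | Iterable[PredictorSpec],
) -> ScoreTable:
    """Score every candidate; deterministic (sorted) iteration order.

    Raises
    ------
    ValueError
        If any candidate is already an observed link (offenders listed).
    """
    if isinstance(spec_or_specs, PredictorSpec):
        specs = [spec_or_specs]
        label = spec_or_specs.id
    else:
        specs = list(spec_or_specs)
        if not specs:
            raise ValueError("empty predictor set")
        label = "+".join(s.id for s in specs)
    ordered = sorted(set(candidates), key=lambda a: (str(a[0]), str(a[1])))
    offenders = [a for a in ordered if train.has_edge(*a)]
    if offenders:
        raise ValueError(f"candidates overlap observed links: {offenders[:10]}")
    scores: dict[Arc, int] = {}
    log_every = max(1, len(ordered) // 10)
    for i, arc in enumerate(ordered):
        scores[arc] = sum(score_link_fast(train, arc, s) for s in specs)
        if (i + 1) % log_every == 0:
            logger.debug("scored %d/%d candidates (%s)", i + 1, len(ordered), label)
    return ScoreTable(predictor_id=label, scores=scores)


def count_occurrences(g: nx.DiGraph, pattern: PatternGraph) -> int:
    """Brute-force count of generalized occurrences of a pattern in ``g``.

    Injective role maps with every pattern arc present, divided by the
    automorphism group order.  Independent of the scoring path; used as a
    direct created-subgraph oracle in tests and generator calibration.
    """
    nodes = list(g.nodes)
    count = 0
    for combo in itertools.permutations(nodes, pattern.order):
        if all(g.has_edge(combo[a], combo[b]) for a, b in pattern.arcs):
            count += 1
    return count // len(pattern.automorphisms)
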