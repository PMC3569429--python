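"""Train/probe splitting, AUC computation, and repeated experiments.

The protocol: hide a random 10% of the observed links (the probe set),
score non-observed links on the remaining 90%, and measure the
probability that a random probe (missing) link outscores a random
nonexistent link, counting ties as one half:

    AUC = (n' + 0.5 n'') / n

where over ``n`` comparisons the missing link scores strictly higher
``n'`` times and ties ``n''`` times.  Scores drawn i.i.d. for every link
give AUC ~ 0.5, the pure-chance baseline.  Experiments average over many
independent partitions (50 in the standard protocol).
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from fractions import Fraction
from typing import Hashable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .catalog import PredictorSpec, predictor_by_id, predictor_group
from .predictors import ScoreTable, score_all

logger = logging.getLogger(__name__)

Arc = tuple[Hashable, Hashable]

#: Exact AUC is used when |probe| * |nonexistent| is at most this budget.
EXACT_PAIR_BUDGET = 10_000_000
#: Sample size when the exact budget is exceeded.
SAMPLED_COMPARISONS = 100_000
#: "auto" nonexistent handling enumerates the full universe up to this size,
#: beyond it a uniform sample of 10x the probe size is drawn instead.
AUTO_FULL_NONEXISTENT = 50_000

__all__ = [
    "SplitSpec",
    "AUCResult",
    "split",
    "nonexistent_links",
    "auc_from_counts",
    "auc_sampled",
    "auc_exact",
    "run_experiment",
    "ExperimentResult",
]


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


@dataclass(frozen=True)
class AUCResult:
    """Comparison tallies and the resulting AUC value."""

    n: int
    n_higher: int
    n_equal: int
    auc: float


def split(g: nx.DiGraph, spec: SplitSpec) -> tuple[nx.DiGraph, set[Arc]]:
    """Random 90/10 (by default) partition of the observed arcs.

    The probe size is round-half-up of ``(1 - train_fraction) * M``; the
    probe is drawn uniformly without replacement and is reproducible from
    the seed.  Nodes isolated by the removal stay in the training graph —
    scoring needs the node universe intact.
    """
    m = g.number_of_edges()
    if m < 10:
        raise ValueError(f"graph has {m} arcs; need at least 10 to split")
    n_probe = math.floor((1.0 - spec.train_fraction) * m + 0.5)
    if n_probe == 0:
        raise ValueError(
            f"probe set would be empty (M={m}, train_fraction={spec.train_fraction})"
        )
    arcs = sorted(g.edges(), key=lambda a: (str(a[0]), str(a[1])))
    rng = np.random.default_rng(spec.seed)
    idx = rng.choice(m, size=n_probe, replace=False)
    probe = {arcs[i] for i in idx}
    train = g.copy()
    train.remove_edges_from(probe)
    return train, probe


def nonexistent_links(
    g: nx.DiGraph, sample: int | None = None, seed: int = 0
) -> set[Arc]:
    """Ordered node pairs never linked in ``g`` (the nonexistent links).

    With ``sample`` set, draws that many uniformly without replacement
    instead of enumerating the full quadratic universe.
    """
    nodes = sorted(g.nodes, key=str)
    universe = [
        (u, v) for u in nodes for v in nodes if u != v and not g.has_edge(u, v)
    ]
    if sample is None or sample >= len(universe):
        return set(universe)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(universe), size=sample, replace=False)
    return {universe[i] for i in idx}


def auc_from_counts(n: int, n_higher: int, n_equal: int) -> AUCResult:
    """AUC = (n' + 0.5 n'') / n, in exact rational arithmetic."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n_higher < 0 or n_equal < 0 or n_higher + n_equal > n:
        raise ValueError("require 0 <= n_higher + n_equal <= n")
    auc = Fraction(2 * n_higher + n_equal, 2 * n)
    return AUCResult(n=n, n_higher=n_higher, n_equal=n_equal, auc=float(auc))


def _score_lookup(scores: ScoreTable | Mapping[Arc, float]) -> Mapping[Arc, float]:
    return scores.scores if isinstance(scores, ScoreTable) else scores


def _gather(scores: Mapping[Arc, float], arcs: Iterable[Arc]) -> list[float]:
    vals = []
    for a in arcs:
        if a not in scores:
            raise ValueError(f"arc {a!r} has no score")
        vals.append(scores[a])
    return vals


def auc_sampled(
    scores: ScoreTable | Mapping[Arc, float],
    probe: Sequence[Arc] | set[Arc],
    nonexistent: Sequence[Arc] | set[Arc],
    n_comparisons: int,
    seed: int = 0,
) -> AUCResult:
    """AUC from independent uniform (missing, nonexistent) comparisons."""
    lookup = _score_lookup(scores)
    p = np.asarray(_gather(lookup, sorted(probe, key=str)), dtype=float)
    q = np.asarray(_gather(lookup, sorted(nonexistent, key=str)), dtype=float)
    if p.size == 0 or q.size == 0:
        raise ValueError("probe and nonexistent sets must be non-empty")
    rng = np.random.default_rng(seed)
    ps = p[rng.integers(0, p.size, size=n_comparisons)]
    qs = q[rng.integers(0, q.size, size=n_comparisons)]
    n_higher = int(np.count_nonzero(ps > qs))
    n_equal = int(np.count_nonzero(ps == qs))
    return auc_from_counts(n_comparisons, n_higher, n_equal)


def auc_exact(
    scores: ScoreTable | Mapping[Arc, float],
    probe: Sequence[Arc] | set[Arc],
    nonexistent: Sequence[Arc] | set[Arc],
) -> AUCResult:
    """Exact AUC over all |probe| x |nonexistent| ordered comparisons.

    Equivalent to the Mann-Whitney midrank statistic; computed by binary
    search on the sorted nonexistent scores, so cost is
    O((n1 + n2) log n2) instead of the full pair product.
    """
    lookup = _score_lookup(scores)
    p = _gather(lookup, sorted(probe, key=str))
    q = sorted(_gather(lookup, sorted(nonexistent, key=str)))
    if not p or not q:
        raise ValueError("probe and nonexistent sets must be non-empty")
    n_higher = 0
    n_equal = 0
    for s in p:
        lo = bisect_left(q, s)
        n_higher += lo
        n_equal += bisect_right(q, s) - lo
    return auc_from_counts(len(p) * len(q), n_higher, n_equal)


@dataclass(frozen=True)
class ExperimentResult:
    """Per-predictor summary plus full per-repetition provenance."""

    summary: pd.DataFrame  # index: predictor label; columns: mean_auc, std_auc
    details: pd.DataFrame  # one row per (repetition, predictor)


def _resolve_predictor_set(
    entry,
) -> tuple[str, list[PredictorSpec]]:
    """Accept 'S5', a parent name, a PredictorSpec, or a list of any."""
    if isinstance(entry, PredictorSpec):
        return entry.id, [entry]
    if isinstance(entry, str):
        try:
            return entry, [predictor_by_id(entry)]
        except KeyError:
            group = predictor_group(entry)
            return group[0].parent.name, list(group)
    specs = []
    for item in entry:
        specs.extend(_resolve_predictor_set(item)[1])
    if not specs:
        raise ValueError("empty predictor set")
    return "+".join(s.id for s in specs), specs


def run_experiment(
    g: nx.DiGraph,
    predictor_sets: Sequence,
    repetitions: int = 50,
    base_seed: int = 0,
    train_fraction: float = 0.9,
    nonexistent_sample: int | str = "auto",
    exact_pair_budget: int = EXACT_PAIR_BUDGET,
    sampled_comparisons: int = SAMPLED_COMPARISONS,
) -> ExperimentResult:
    """Repeated random-partition evaluation of one or more predictors.

    For each repetition ``r`` the graph is split with seed
    ``base_seed + r``, every predictor set is scored on the training
    graph over probe plus nonexistent candidates, and the AUC is exact
    whenever the comparison universe fits ``exact_pair_budget`` (else
    sampled with ``sampled_comparisons`` draws, logged).  Nonexistent
    links are enumerated fully when ``nonexistent_sample`` is ``"all"``
    and uniformly sampled when it is an integer; the default ``"auto"``
    enumerates fully while the universe fits ``AUTO_FULL_NONEXISTENT``
    pairs and otherwise samples 10x the probe size (the quadratic
    candidate universe is infeasible on large graphs).

    Identical arguments give bit-identical result tables.
    """
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    resolved = [_resolve_predictor_set(e) for e in predictor_sets]
    rows = []
    n = g.number_of_nodes()
    universe = n * (n - 1) - g.number_of_edges()
    for r in range(repetitions):
        seed = base_seed + r
        train, probe = split(g, SplitSpec(train_fraction=train_fraction, seed=seed))
        if nonexistent_sample == "all":
            sample = None
        elif nonexistent_sample == "auto":
            sample = None if universe <= AUTO_FULL_NONEXISTENT else 10 * len(probe)
        else:
            sample = int(nonexistent_sample)
        nonexist = nonexistent_links(g, sample=sample, seed=seed + 1)
        nonexist -= probe
        candidates = probe | nonexist
        for label, specs in resolved:
            table = score_all(train, candidates, specs)
            n_pairs = len(probe) * len(nonexist)
            if n_pairs <= exact_pair_budget:
                res = auc_exact(table, probe, nonexist)
                mode = "exact"
            else:
                res = auc_sampled(
                    table, probe, nonexist, sampled_comparisons, seed=seed + 2
                )
                mode = "sampled"
                logger.info(
                    "rep %d %s: sampled AUC with %d comparisons "
                    "(pair universe %d exceeds budget)",
                    r, label, sampled_comparisons, n_pairs,
                )
            rows.append(
                {
                    "repetition": r,
                    "predictor": label,
                    "auc": res.auc,
                    "n_comparisons": res.n,
                    "mode": mode,
                    "split_seed": seed,
                    "n_probe": len(probe),
                    "n_nonexistent": len(nonexist),
                }
            )
    details = pd.DataFrame(rows)
    summary = (
        details.groupby("predictor", sort=False)["auc"]
        .agg(mean_auc="mean", std_auc="std")
        .fillna({"std_auc": 0.0})
    )
    return ExperimentResult(summary=summary, details=details)
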