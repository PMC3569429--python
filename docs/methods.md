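# Methods

## Model

The package operates on unweighted simple digraphs: duplicate arcs
collapse, self-loops are dropped at load time (no catalog pattern
contains one, and food-web cannibalism loops would otherwise make the
potential rule vacuous), reciprocal pairs are kept.  Node identifiers
are opaque; all algorithms are purely topological.

**Potentials.**  A graph is potential-definable when integers `phi` with
`phi(u) = phi(v) + 1` for every arc `u -> v` exist.  The assignment is
computed by breadth-first labelling over the underlying undirected
graph (each arc traversed forward steps `phi` down one, backward up
one), which is linear in nodes plus arcs.  The rule fixes only
differences, so potentials are normalized to minimum 0 within each
weakly connected component; a disconnected graph is definable iff every
component is, since the rule imposes no cross-component constraint.
Non-definability is certified by a witness: a closed walk (the BFS tree
path between the endpoints of the first conflicting arc, plus that arc)
whose signed unit steps do not sum to zero.  Definable graphs are
necessarily acyclic, and a graph is definable iff every undirected
cycle traverses equal numbers of forward and backward arcs — both facts
are exercised as test oracles.

**Subgraph catalog.**  Subgraphs are *generalized*: any node subset
together with any subset of the arcs among those nodes (not only
induced subgraphs).  A pattern is loop-embedded when its undirected
skeleton contains a cycle, with reciprocal pairs not counting as loops
and barred from patterns outright (a pattern containing one would
contain a disallowed 2-loop).  Minimality — no proper generalized
subgraph is loop-embedded — is decided against the maximal proper
subgraphs only (drop one arc, or one node), which is sufficient because
loop-embeddedness is monotone under inclusion; the test suite re-checks
the published catalog against the full exhaustive subset search.
Enumeration is brute force over all reciprocal-free digraphs on 3 or 4
labelled nodes, deduplicated by a canonical form (minimum relabelled
arc tuple over all node permutations — at most 24, so exact and cheap).
The skeleton of every survivor is a single Hamiltonian cycle, and the
six classes match the documented role representatives.

**Predictors.**  Each of the twelve predictors is a (pattern, arc-orbit)
pair; the orbit representative is the minimum arc in the documented
role order.  Any consistent representative choice yields the same
predictor because occurrences are counted modulo automorphisms.  The
labels within a parent group (S1–S3, S6–S7, S9–S12) follow this
canonical arc order.  Scoring counts injective role maps with the
candidate pinned to the probe arc; the automorphism stabilizer of every
probe arc is trivial (asserted at catalog build time), so the count
reduces to counting assignments of the one or two free roles.  The fast
path intersects adjacency sets per free role and, for order-4 patterns,
sums matches over the arc joining the two free roles; its worst case is
the product of two adjacency-list sizes.  A transparent brute-force
enumerator is kept as the reference and is pinned to the fast path over
randomized instances in the tests.  The presence of a reverse arc
`y -> x` never affects the score of candidate `x -> y` (reciprocity is
deliberately set aside by the model).

## Evaluation protocol

Observed arcs are split uniformly at random into 90% training / 10%
probe (probe size is round-half-up of `0.1 M`, documented because `M`
is rarely divisible by 10); nodes isolated by the removal stay in the
training graph so the candidate universe is intact.  Nonexistent links
are all ordered never-linked pairs; above 50,000 pairs the default
("auto") draws a uniform sample of 10x the probe size instead, since
the universe grows quadratically.  AUC is computed exactly (midrank
statistic over all probe x nonexistent pairs, exact integer tallies of
higher/tied comparisons) whenever that product is at most 10^7,
otherwise from 10^5 sampled comparisons; both paths are logged and both
sizes are configurable.  Experiments repeat over `base_seed + r` for
repetition `r`, and identical inputs give bit-identical result tables.

## Synthetic generators

The generators stand in for the regimes the method targets — sparse
directed networks at food-web scale (tens to hundreds of nodes, average
degree roughly 3–15):

- `random_digraph` — uniform simple digraph with an exact arc count
  (sampled without replacement, so test assertions are crisp) or an
  independent arc probability; optional reciprocal-free mode.
- `layered_dag` — nodes split evenly across `L` layers, arcs only from
  layer `l+1` to `l`; potential-definable by construction and recovers
  its layer indices up to a per-component shift.
- `planted_bifan_graph` — bipartite source→sink graph with independent
  arc inclusion; expected Bi-fan count `C(S,2) C(T,2) p^4` is attached
  as metadata and validated empirically.

What they do **not** emulate: degree heterogeneity (hubs), reciprocity
bursts, clustering beyond what density implies, and community
structure.  Passing tests therefore demonstrate correctness of the
machinery and recoverability of planted structure, not predictive
performance on any real network; real edge lists can be run through the
same CLI for that.

Default study conditions used by the tests and the acceptance script:
random-baseline calibration on 50 nodes / 300 arcs (90/10 split, 10,000
sampled comparisons per seed, 20 seeds); planted-structure recovery on
30+30 bipartite nodes at arc probability 0.3 with exact AUC over 10
splits; protocol reproducibility on 200 nodes / 1,000 arcs with 50
partitions and a 1,000-link nonexistent sample.  These sizes keep every
run at desk scale while leaving the statistics well-resolved (the
random-baseline mean has standard error ~0.012).

## Numerical and design choices

- Effective diameter is the linearly interpolated 90th percentile of
  finite ordered-pair BFS distances (exact all-pairs BFS, not a
  probabilistic counter: target graphs are small).  Directed clustering
  is Fagiolo's coefficient averaged over nodes, with total-degree-<2
  nodes contributing 0.
- Component ties in largest-WCC extraction break toward the component
  holding the lexicographically smallest node label.
- AUC tallies use exact integer counts and rational arithmetic before
  the final float conversion.
- Pajek `*Edges` lines expand to reciprocal arc pairs — an undirected
  line in a directed container has no other faithful reading.
- Fixture node labels are lowercase letters in role-index order so
  worked examples are stable.

## Limitations

- Catalog and predictors cover orders 3–4 only; order ≥ 5 patterns and
  motif-significance profiling against randomized ensembles are out of
  scope.
- Scores are integer counts; no weighting, recency, or probabilistic
  calibration.
- Exact AUC above the pair budget falls back to sampling; on
  million-node graphs the nonexistent sample size is the main accuracy
  knob and is the caller's responsibility.
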