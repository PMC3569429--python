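import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from potnet import (
    GeneratorConfig,
    SplitSpec,
    auc_exact,
    auc_from_counts,
    auc_sampled,
    nonexistent_links,
    planted_bifan_graph,
    random_digraph,
    run_experiment,
    split,
)


@pytest.fixture(scope="module")
def medium_graph():
    return random_digraph(GeneratorConfig(n_nodes=50, n_arcs=300, seed=42))


class TestSplit:
    def test_90_10_sizes(self):
        g = random_digraph(GeneratorConfig(n_nodes=30, n_arcs=100, seed=0))
        train, probe = split(g, SplitSpec(train_fraction=0.9, seed=1))
        assert len(probe) == 10
        assert train.number_of_edges() == 90
        assert set(train.edges()) | probe == set(g.edges())
        assert set(train.edges()).isdisjoint(probe)

    def test_same_seed_same_partition(self, medium_graph):
        t1, p1 = split(medium_graph, SplitSpec(seed=5))
        t2, p2 = split(medium_graph, SplitSpec(seed=5))
        assert p1 == p2
        assert set(t1.edges()) == set(t2.edges())

    def test_different_seeds_differ(self, medium_graph):
        _, p1 = split(medium_graph, SplitSpec(seed=5))
        _, p2 = split(medium_graph, SplitSpec(seed=6))
        assert p1 != p2

    def test_isolated_nodes_retained(self):
        g = random_digraph(GeneratorConfig(n_nodes=12, n_arcs=12, seed=3))
        train, _ = split(g, SplitSpec(train_fraction=0.9, seed=0))
        assert set(train.nodes) == set(g.nodes)

    def test_empty_probe_guard(self):
        g = random_digraph(GeneratorConfig(n_nodes=12, n_arcs=10, seed=0))
        with pytest.raises(ValueError, match="empty"):
            split(g, SplitSpec(train_fraction=0.99, seed=0))

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)


class TestAUCFromCounts:
    def test_formula(self):
        assert auc_from_counts(100, 80, 10).auc == pytest.approx(0.85)

    def test_all_ties_is_half(self):
        assert auc_from_counts(64, 0, 64).auc == 0.5

    def test_perfect_separation(self):
        assert auc_from_counts(64, 64, 0).auc == 1.0

    def test_count_violations_rejected(self):
        with pytest.raises(ValueError):
            auc_from_counts(0, 0, 0)
        with pytest.raises(ValueError):
            auc_from_counts(10, 8, 5)


class TestAUCExact:
    def test_four_pair_example(self):
        # probe scores {3, 1}, nonexistent {2, 0}: higher 3 of 4, lower 1
        scores = {"p1": 3, "p2": 1, "q1": 2, "q2": 0}
        res = auc_exact(scores, ["p1", "p2"], ["q1", "q2"])
        assert res.n == 4
        assert res.n_higher == 3
        assert res.n_equal == 0
        assert res.auc == pytest.approx(0.75)

    def test_all_equal_scores(self):
        scores = {k: 7 for k in "abcdef"}
        assert auc_exact(scores, ["a", "b"], ["c", "d", "e"]).auc == 0.5

    def test_unscored_arc_rejected(self):
        with pytest.raises(ValueError, match="no score"):
            auc_exact({"a": 1}, ["a"], ["b"])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_antisymmetry_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        probe = [("p", i) for i in range(5)]
        nonex = [("q", i) for i in range(7)]
        scores = {a: int(v) for a, v in zip(probe + nonex, rng.integers(0, 4, 12))}
        fwd = auc_exact(scores, probe, nonex)
        rev = auc_exact(scores, nonex, probe)
        assert 0.0 <= fwd.auc <= 1.0
        assert fwd.auc + rev.auc == pytest.approx(1.0)


class TestAUCSampled:
    def test_deterministic_dominance(self):
        scores = {"a": 5, "b": 5, "c": 3}
        res = auc_sampled(scores, ["a", "b"], ["c"], n_comparisons=500, seed=0)
        assert res.auc == 1.0

    def test_single_tie(self):
        res = auc_sampled({"a": 2, "b": 2}, ["a"], ["b"], n_comparisons=100, seed=0)
        assert res.auc == 0.5

    def test_reproducible(self):
        rng = np.random.default_rng(0)
        scores = {("x", i): float(v) for i, v in enumerate(rng.random(40))}
        arcs = list(scores)
        r1 = auc_sampled(scores, arcs[:10], arcs[10:], 1000, seed=9)
        r2 = auc_sampled(scores, arcs[:10], arcs[10:], 1000, seed=9)
        assert (r1.n_higher, r1.n_equal) == (r2.n_higher, r2.n_equal)

    def test_within_three_standard_errors_of_exact(self):
        rng = np.random.default_rng(3)
        scores = {("s", i): float(v) for i, v in enumerate(rng.random(60))}
        arcs = list(scores)
        probe, nonex = arcs[:15], arcs[15:]
        exact = auc_exact(scores, probe, nonex).auc
        n = 20_000
        sampled = auc_sampled(scores, probe, nonex, n, seed=4).auc
        se = np.sqrt(exact * (1 - exact) / n) + 1e-9
        assert abs(sampled - exact) <= 3 * se + 0.01

    def test_iid_scores_give_half(self, medium_graph):
        # one probe draw has SD ~ sqrt((n1+n2)/(12 n1 n2)) ~ 0.05 at
        # |probe|=30, so average several independent splits and score draws
        aucs = []
        for seed in range(10):
            _, probe = split(medium_graph, SplitSpec(seed=seed))
            nonex = nonexistent_links(medium_graph)
            rng = np.random.default_rng(100 + seed)
            arcs = sorted(probe | nonex, key=str)
            scores = dict(zip(arcs, rng.random(len(arcs))))
            aucs.append(auc_sampled(scores, probe, nonex, 5_000, seed=seed).auc)
        assert abs(float(np.mean(aucs)) - 0.5) < 0.05


class TestRunExperiment:
    def test_bit_identical_reproducibility(self, medium_graph):
        kwargs = dict(repetitions=5, base_seed=17, nonexistent_sample=200)
        r1 = run_experiment(medium_graph, ["S5", "S1"], **kwargs)
        r2 = run_experiment(medium_graph, ["S5", "S1"], **kwargs)
        assert r1.summary.equals(r2.summary)
        assert r1.details.equals(r2.details)

    def test_partitions_are_independent(self, medium_graph):
        probes = [
            frozenset(split(medium_graph, SplitSpec(seed=s))[1]) for s in range(10)
        ]
        assert len(set(probes)) == 10

    def test_single_repetition_fixed_seed(self, medium_graph):
        res = run_experiment(medium_graph, ["S5"], repetitions=1, base_seed=3,
                             nonexistent_sample=150)
        assert len(res.details) == 1
        assert res.summary.loc["S5", "std_auc"] == 0.0
        assert 0.0 <= res.summary.loc["S5", "mean_auc"] <= 1.0

    def test_bifan_predictor_beats_triangle_predictor_on_planted_graph(self):
        """In a two-layer source->sink graph no directed triangle can close,
        so the 3-Loop predictor is all ties (0.5) while Bi-fan recovers
        planted structure."""
        g = planted_bifan_graph(12, 12, 0.35, seed=5)
        res = run_experiment(g, ["S5", "S4"], repetitions=5, base_seed=0)
        assert res.summary.loc["S4", "mean_auc"] == 0.5
        assert res.summary.loc["S5", "mean_auc"] > res.summary.loc["S4", "mean_auc"]

    def test_parent_name_resolves_to_hybrid(self, medium_graph):
        res = run_experiment(medium_graph, ["3-FFL"], repetitions=2, base_seed=0,
                             nonexistent_sample=100)
        assert list(res.summary.index) == ["3-FFL"]
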