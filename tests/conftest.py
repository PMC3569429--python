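import pytest

from potnet import GeneratorConfig, random_digraph


@pytest.fixture
def tiny_edgelist(tmp_path):
    """A small two-component edge list on disk."""
    p = tmp_path / "tiny.txt"
    p.write_text("# comment\na b\nb c\nd e\n")
    return p


def random_graphs(n_graphs, seed0=0, n_range=(10, 30), density_range=(0.05, 0.4)):
    """Seeded batch of random digraphs spanning a density band."""
    import numpy as np

    rng = np.random.default_rng(seed0)
    for k in range(n_graphs):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        p = float(rng.uniform(*density_range))
        yield random_digraph(
            GeneratorConfig(n_nodes=n, arc_probability=p, seed=seed0 + 1000 + k)
        )
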