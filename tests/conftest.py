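import numpy as np
import pytest

from deepphylo.simulate import simulate_tree
from deepphylo.table import AbundanceTable


def random_tree(n_leaves: int, seed: int):
    """Random birth-death tree used across test modules."""
    return simulate_tree(n_leaves, seed)


@pytest.fixture
def small_tree():
    from deepphylo.tree import PhyloTree

    return PhyloTree.from_newick("((A:1.0,B:2.0):0.5,C:3.0);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(values, otus=None, samples=None) -> AbundanceTable:
    values = np.asarray(values, dtype=float)
    m, n = values.shape
    otus = otus or [f"O{i}" for i in range(m)]
    samples = samples or [f"S{j}" for j in range(n)]
    return AbundanceTable(values, otus, samples)
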