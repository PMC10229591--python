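import numpy as np
import pytest

from florealm.beta import pairwise_beta
from florealm.containers import BetaMatrix, OccurrenceMatrix
from florealm.synthetic import simulate_world
from florealm.tree import DatedTree


@pytest.fixture(scope="session")
def toy_tree() -> DatedTree:
    """Three tips, crown age 2: ((A:1,B:1):1,C:2)."""
    return DatedTree.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def default_world():
    """The standard planted world: 4 realms, 6x6 GSUs, 200 genera."""
    return simulate_world(seed=11)


@pytest.fixture(scope="session")
def default_beta(default_world):
    return pairwise_beta(
        default_world.occurrences, tree=default_world.tree,
        mode="phylogenetic",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_beta_matrix(rng, n: int) -> BetaMatrix:
    """A random valid dissimilarity matrix in [0, 1]."""
    vals = rng.random((n, n))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 0.0)
    return BetaMatrix([f"u{i:02d}" for i in range(n)], vals)


def block_beta_matrix(n_per_block: int, n_blocks: int = 2) -> BetaMatrix:
    """Exact block matrix: 0 within, 1 between."""
    n = n_per_block * n_blocks
    vals = np.ones((n, n))
    for b in range(n_blocks):
        s = slice(b * n_per_block, (b + 1) * n_per_block)
        vals[s, s] = 0.0
    np.fill_diagonal(vals, 0.0)
    return BetaMatrix([f"u{i:02d}" for i in range(n)], vals)


def random_occurrence(rng, n_genera: int, n_gsus: int) -> OccurrenceMatrix:
    while True:
        data = rng.random((n_genera, n_gsus)) < 0.5
        if data.any(axis=1).all() and data.any(axis=0).all():
            return OccurrenceMatrix(
                [f"t{i:04d}" for i in range(1, n_genera + 1)],
                [f"g{j:02d}" for j in range(n_gsus)],
                data,
            )
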