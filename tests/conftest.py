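import numpy as np
import pytest

from phylogan.datamodel import AbundanceTable, TaxonomyTree
from phylogan.fixtures import FixtureSpec, block_correlation, make_fixture


@pytest.fixture(scope="session")
def small_fixture():
    """40 samples x 12 species with two correlated blocks and 50% masking."""
    spec = FixtureSpec(
        n_samples=40, n_species=12,
        correlation=block_correlation(12, 2, 0.6),
        zero_inflation=0.5, seed=3,
    )
    table, tree, truth = make_fixture(spec)
    return spec, table, tree, truth


def random_tree(rng: np.random.Generator, max_leaves: int = 10) -> TaxonomyTree:
    """Random rooted tree by recursive attachment, with random branch lengths."""
    while True:
        n_nodes = int(rng.integers(3, 2 * max_leaves))
        parent = {}
        children = {}
        names = [f"n{i}" for i in range(n_nodes)]
        for i in range(1, n_nodes):
            p = names[int(rng.integers(0, i))]
            parent[names[i]] = p
            children.setdefault(p, []).append(names[i])
        lengths = {names[i]: float(rng.uniform(0.1, 2.0)) for i in range(1, n_nodes)}
        tree = TaxonomyTree(root=names[0], parent=parent, children=children,
                            branch_lengths=lengths)
        if 2 <= len(tree.leaves()) <= max_leaves:
            return tree


def random_composition(rng: np.random.Generator, n: int, p: int,
                       zero_prob: float = 0.3) -> np.ndarray:
    x = rng.dirichlet(np.ones(p), size=n)
    mask = rng.uniform(size=(n, p)) >= zero_prob
    for i in range(n):
        if not mask[i].any():
            mask[i, int(rng.integers(0, p))] = True
    x = x * mask
    return x / x.sum(axis=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
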