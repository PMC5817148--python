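import numpy as np
import pytest

from traitrates import synthdata
from traitrates.mklik import QMatrix, RootPrior
from traitrates.treeio import TraitData, parse_newick


@pytest.fixture
def uniform_pi():
    return RootPrior.uniform(5)


@pytest.fixture
def cherry_tree():
    return parse_newick("((a:1,b:1):1,c:2);")


@pytest.fixture
def zero_cherry():
    """Two-leaf tree with zero-length branches."""
    return parse_newick("(a:0,b:0);")


@pytest.fixture
def small_scenario():
    return synthdata.wolbachia_like_scenario("small", seed=0)


def random_instance(rng, n_min=2, n_max=6, rate_hi=2.0):
    """One random (tree, Q, traits) triple for oracle cross-checks.

    Mixes in polytomies (by collapsing a random internal edge) and
    zero-length branches.
    """
    n = int(rng.integers(n_min, n_max + 1))
    tree = synthdata.simulate_yule_tree(n, 1.0, seed=int(rng.integers(1 << 30)))
    # random polytomy: collapse one internal non-root node
    internals = [x for x in tree.internal_nodes() if x.parent is not None]
    if internals and rng.random() < 0.4:
        victim = internals[int(rng.integers(len(internals)))]
        parent = victim.parent
        idx = parent.children.index(victim)
        parent.children.pop(idx)
        for child in victim.children:
            child.parent = parent
            parent.children.append(child)
    # random zero-length branches
    for node in tree.postorder():
        if node.parent is not None and rng.random() < 0.15:
            node.length = 0.0
    off = rng.uniform(0.0, rate_hi, (5, 5))
    off[rng.random((5, 5)) < 0.2] = 0.0  # structural zeros
    Q = QMatrix.from_off_diagonal(off)
    pi = RootPrior.uniform(5)
    traits, _ = synthdata.simulate_trait(tree, Q, pi, seed=int(rng.integers(1 << 30)))
    return tree, Q, traits
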