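import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from phylotraits import parse_newick, yule_tree


@pytest.fixture
def three_tip():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced4():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def star5():
    return parse_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture
def caterpillar5():
    return parse_newick("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")


@pytest.fixture
def tree10():
    return yule_tree(10, seed=42)


def random_tree(n_tips, seed, clock=True, rate_sd=0.0):
    """A Yule tree, optionally with lognormal rate perturbation per edge."""
    tree = yule_tree(n_tips, seed)
    if not clock or rate_sd > 0:
        rng = np.random.default_rng(seed + 10_000)
        for node in tree.preorder():
            if node.parent is not None:
                node.length *= rng.lognormal(0.0, rate_sd if rate_sd > 0 else 0.5)
    return tree
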