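import numpy as np
import pytest

from climevol.treekit import parse_newick


@pytest.fixture
def balanced_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def five_tip_tree():
    return parse_newick("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")


@pytest.fixture
def star_tree_factory():
    def make(labels, depth=3.0):
        return parse_newick("(" + ",".join(f"{l}:{depth}" for l in labels) + ");")

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
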