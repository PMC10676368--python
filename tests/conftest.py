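import numpy as np
import pytest

from earevol import synth
from earevol.trees import TreeArrays


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_tree():
    return synth.make_fixture_tree()


@pytest.fixture
def tiny_tree():
    """3-tip tree ((A:1,B:1):1,C:2) with hand-computable covariance."""
    return TreeArrays.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star2():
    return TreeArrays.from_newick("(A:1,B:1);")


def random_trees(n_trees, n_tips, seed, mean_depth=10.0):
    rng = np.random.default_rng(seed)
    return [synth.random_tree(n_tips, rng, mean_depth=mean_depth)
            for _ in range(n_trees)]
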