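import numpy as np
import pytest

from islandpcm import synthetic, treeio


@pytest.fixture
def cherry():
    """Two-tip tree, both branches length 1 (identity covariance)."""
    return treeio.read_newick("(A:1.0,B:1.0);")


@pytest.fixture
def three_tip():
    """Ultrametric 3-tip tree of depth 2."""
    return treeio.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def fixture_dataset():
    """The 48-tip study fixture: tree, painting, traits, groups."""
    return synthetic.study_fixture(20260101)


@pytest.fixture(scope="session")
def fixture_tree(fixture_dataset):
    return fixture_dataset[0]


@pytest.fixture(scope="session")
def fixture_painting(fixture_dataset):
    return fixture_dataset[1]


def random_yule(n_tips, seed):
    return synthetic.yule_tree(n_tips, seed)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
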