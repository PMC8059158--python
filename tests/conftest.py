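import numpy as np
import pytest

import convmorph as cm
from convmorph.phylo import Phylogeny


@pytest.fixture(scope="session")
def small_study():
    """Deterministic miniature study: 8 species x 3 specimens x 20 landmarks."""
    return cm.fixture_small()


@pytest.fixture(scope="session")
def aligned_small(small_study):
    return cm.gpa_align(small_study.configs)


@pytest.fixture(scope="session")
def three_tip_tree():
    """((A:1,B:1):1,C:2); — the hand-computable workhorse tree."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_yule(n_tips, seed):
    from convmorph.synthetic import yule_tree

    return yule_tree(n_tips, np.random.default_rng(seed))
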