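import logging

import numpy as np
import pytest

import phenophylo as pp

logging.getLogger("phenophylo").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def balanced4():
    """((A:1,B:1):1,(C:1,D:1):1) — the hand-checkable 4-tip tree."""
    return pp.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture(scope="session")
def caterpillar3():
    return pp.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def star_tree():
    def make(n=4, t=1.0):
        tips = ",".join(f"t{i}:{t}" for i in range(n))
        return pp.parse_newick(f"({tips});")

    return make


@pytest.fixture(scope="session")
def yule64():
    return pp.simulate_yule_tree(64, seed=20240)


@pytest.fixture(scope="session")
def yule64_cov(yule64):
    return pp.phylo_covariance(yule64)
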