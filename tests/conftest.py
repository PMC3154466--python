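import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phylorisk import Phylogeny

settings.register_profile(
    "default", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def balanced4():
    """4-tip balanced tree, every non-root edge 0.5, depth 1."""
    return Phylogeny.from_newick("((A:0.5,B:0.5):0.5,(C:0.5,D:0.5):0.5);")


@pytest.fixture
def star4():
    """Bifurcating tree in the star limit: all splits at the root (zero internal edges)."""
    return Phylogeny.from_newick("((A:1,B:1):0,(C:1,D:1):0);")


@pytest.fixture
def two_tip():
    return Phylogeny.from_newick("(A:1,B:1);")
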