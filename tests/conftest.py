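import numpy as np
import pytest

from phylodisp import Phylogeny, simulate_tree


@pytest.fixture
def cherry():
    """Two-tip tree of depth 1."""
    return Phylogeny.from_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    """((A,B),C) with d(A,B)=2 and d(A,C)=d(B,C)=4."""
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree41():
    """A 41-tip ultrametric Yule tree, the pool size of the emulated plot."""
    return simulate_tree(41, depth=100.0, seed=2024)


@pytest.fixture(scope="session")
def tree50():
    """Fixed 50-tip tree used for Brownian-calibration checks."""
    return simulate_tree(50, depth=100.0, seed=77)


def star_tree(n: int, depth: float = 1.0) -> Phylogeny:
    """Star phylogeny: all tips attach directly to the root."""
    tips = ",".join(f"t{i}:{depth}" for i in range(n))
    return Phylogeny.from_newick(f"({tips});")


@pytest.fixture
def star8():
    return star_tree(8)
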