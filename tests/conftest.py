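import numpy as np
import pytest

from copynorm import TraitTree


@pytest.fixture
def three_tip_tree():
    """((A:1,B:2)N:1,C:3)R — the worked PIC example tree."""
    return TraitTree.from_newick("((A:1,B:2)N:1,C:3)R;")


@pytest.fixture
def three_tip_traits():
    return {"A": 2.0, "B": 4.0, "C": 8.0}


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
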