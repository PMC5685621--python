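import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/oracles.py

from aftree.io_formats import DistanceMatrix, SequenceRecord
from aftree.phylo import patristic_matrix
from aftree.simulate import simulate_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20260905)


@pytest.fixture
def toy_pair():
    return SequenceRecord("X", "TCTGA"), SequenceRecord("Y", "CCTGT")


@pytest.fixture
def kr_pair():
    return SequenceRecord("X", "TCTGA"), SequenceRecord("Y", "TCGGT")


def random_additive_instance(seed, n_taxa):
    """A random tree with exponential branch lengths and its exact patristic matrix."""
    tree = simulate_tree(n_taxa, seed)
    dm = patristic_matrix(tree)
    return tree, dm


@pytest.fixture
def additive_four_taxon():
    # ((A:1,B:2):1,(C:3,D:4)) -> d_AB=3, d_AC=5, d_AD=6, d_BC=6, d_BD=7, d_CD=7
    labels = list("ABCD")
    values = np.array(
        [[0, 3, 5, 6],
         [3, 0, 6, 7],
         [5, 6, 0, 7],
         [6, 7, 7, 0]], dtype=float)
    return DistanceMatrix(values, labels)
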