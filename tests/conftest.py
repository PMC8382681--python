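import numpy as np
import pytest

from phylomosaic import seqio, synthetic_data as sd
from phylomosaic.supermatrix import Alignment


@pytest.fixture
def two_marker_alignments():
    m1 = Alignment("m1", {"X": "ACGT", "Y": "ACGA"})
    m2 = Alignment("m2", {"Y": "TTTTGG", "Z": "TTCTGG"})
    return [m1, m2]


@pytest.fixture
def quartet_tree():
    return seqio.read_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def six_leaf_tree():
    return seqio.read_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")


def random_resolved_tree(n_leaves: int, seed: int):
    """A random bifurcating tree with branch lengths, via the Yule simulator."""
    return sd.simulate_yule_tree(n_leaves, birth_rate=1.0, seed=seed)


def random_alignment(n_taxa: int, length: int, seed: int, marker: str = "rand"):
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT-?N"))
    probs = np.array([0.2, 0.2, 0.2, 0.2, 0.1, 0.05, 0.05])
    rows = {
        f"t{i}": "".join(rng.choice(alphabet, size=length, p=probs))
        for i in range(n_taxa)
    }
    return Alignment(marker, rows)
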