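import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from cysredox.align import SequenceRecord
from cysredox.synth import SyntheticConfig


@pytest.fixture
def config():
    return SyntheticConfig(seed=11)


SIMPLE_MATRIX = {
    (x, y): (1.0 if x == y else -1.0)
    for x in "ACDEFGHIKLMNPQRSTVWYX"
    for y in "ACDEFGHIKLMNPQRSTVWYX"
}


@pytest.fixture
def simple_matrix():
    """Match +1 / mismatch -1 scoring, used with gap_open == gap_extend for linear gaps."""
    return SIMPLE_MATRIX


@pytest.fixture
def shp1_like_pair():
    """Synthetic stand-in for the SHP1 mouse/human ortholog pair.

    Both sequences carry a cysteine at position 102 in an identical local
    context; divergence (substitutions and one insertion) is placed well away
    from it, so a correct residue map must contain (102, 102).
    """
    rng = np.random.default_rng(102)
    aas = list("ADEFGHIKLMNPQRSTVWY")  # no C except where planted
    seq = list(rng.choice(aas, size=250))
    seq[101] = "C"  # 1-based position 102
    seq[49] = "C"
    mouse = "".join(seq)
    human = list(seq)
    human[199] = "A" if human[199] != "A" else "G"  # substitution past the site
    human[219] = "W" if human[219] != "W" else "F"
    human = human[:230] + list("GGS") + human[230:]  # insertion far downstream
    return (
        SequenceRecord("SHP1", "mouse", mouse),
        SequenceRecord("SHP1", "human", "".join(human)),
    )
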