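import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pssmloc.pssm_io import PssmMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_matrix(rng):
    """A raw integer-scale 50 x 20 PSSM."""
    scores = rng.integers(-10, 13, size=(50, 20)).astype(float)
    return PssmMatrix(id="P1", scores=scores)


@pytest.fixture
def small_matrix(rng):
    scores = rng.normal(size=(30, 20))
    return PssmMatrix(id="P1", scores=scores)


def make_ascii_pssm_text(scores, letters="ARNDCQEGHILKMFPSTWYV"):
    """Render a matrix in the PSI-BLAST -out_ascii_pssm layout."""
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(letters) + "   " + "   ".join(letters),
    ]
    for i, row in enumerate(scores, start=1):
        vals = " ".join(f"{int(v):4d}" for v in row)
        pcts = " ".join(f"{0:4d}" for _ in range(20))
        lines.append(f"{i:5d} A  {vals}  {pcts}  0.30 0.10")
    lines += ["", "                      K         Lambda", "Standard Ungapped    0.1 0.3"]
    return "\n".join(lines) + "\n"
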