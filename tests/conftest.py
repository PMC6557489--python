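import numpy as np
import pytest

from crmdecode.sequence_sites import AlignmentMatrix


@pytest.fixture
def sharp_matrix():
    """Near-deterministic 6-bp motif, consensus ACGTAG."""
    counts = np.zeros((6, 4))
    for i, b in enumerate("ACGTAG"):
        counts[i, "ACGT".index(b)] = 90
    return AlignmentMatrix("TFX", counts)


@pytest.fixture
def soft_matrix():
    """Motif with graded preferences at every position (consensus AAAA...)."""
    counts = np.array(
        [
            [70, 10, 15, 5],
            [60, 20, 10, 10],
            [80, 5, 10, 5],
            [70, 10, 10, 10],
            [65, 15, 10, 10],
            [75, 10, 10, 5],
        ],
        dtype=float,
    )
    return AlignmentMatrix("TFY", counts)


def random_matrix(rng: np.random.Generator, name: str = "TFR", length: int = 6):
    """A random informative matrix: one dominant base per position."""
    counts = rng.integers(0, 12, size=(length, 4)).astype(float)
    dom = rng.integers(0, 4, size=length)
    counts[np.arange(length), dom] += 80
    return AlignmentMatrix(name, counts)
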