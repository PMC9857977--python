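import numpy as np
import pytest

from mutexsort import BinaryMatrix


@pytest.fixture
def bm3x4() -> BinaryMatrix:
    """Hand-traceable 3x4 matrix: g1=1100, g2=0011, g3=1010."""
    return BinaryMatrix(
        ["g1", "g2", "g3"],
        ["s1", "s2", "s3", "s4"],
        [[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]],
    )


def identity_bm(n: int) -> BinaryMatrix:
    return BinaryMatrix(
        [f"g{i + 1}" for i in range(n)],
        [f"s{j + 1}" for j in range(n)],
        np.eye(n, dtype=np.int8),
    )


@pytest.fixture
def make_identity():
    return identity_bm
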