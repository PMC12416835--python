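import numpy as np
import pytest

from distseg.io_formats import LabelMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_label_mask(rng, max_side=32, n_seeds=4) -> np.ndarray:
    """Random small instance mask grown from seeds (touching cells allowed)."""
    h = int(rng.integers(4, max_side + 1))
    w = int(rng.integers(4, max_side + 1))
    lab = np.zeros((h, w), dtype=np.int32)
    k = int(rng.integers(0, n_seeds + 1))
    for lbl in range(1, k + 1):
        r, c = int(rng.integers(h)), int(rng.integers(w))
        rad = int(rng.integers(1, 5))
        rr, cc = np.mgrid[0:h, 0:w]
        blob = (rr - r) ** 2 + (cc - c) ** 2 <= rad**2
        lab[blob & (lab == 0)] = lbl
    return lab


@pytest.fixture
def square_cells_mask() -> LabelMask:
    """Two well-separated square cells in a 64x64 frame."""
    lab = np.zeros((64, 64), dtype=np.int32)
    lab[8:20, 8:20] = 1
    lab[36:52, 30:46] = 2
    return LabelMask(labels=lab)
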