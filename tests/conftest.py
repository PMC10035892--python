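import numpy as np
import pytest

from clonefpt.patterns import RED, YELLOW, ClassGrid


@pytest.fixture
def ryr_row():
    """1x3 row red-yellow-red: every CMFPT entry solvable by hand."""
    return ClassGrid(np.array([[RED, YELLOW, RED]], dtype=np.int8))


@pytest.fixture
def checkerboard_54():
    board = np.indices((54, 54)).sum(axis=0) % 2
    return ClassGrid(np.where(board == 0, RED, YELLOW).astype(np.int8))


def random_two_class(shape, phi, seed):
    rng = np.random.default_rng(seed)
    labels = np.where(rng.random(shape) < phi, RED, YELLOW)
    return ClassGrid(labels.astype(np.int8))


@pytest.fixture
def iid_30x30():
    return random_two_class((30, 30), 0.5, seed=3)
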