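import numpy as np
import pytest

from nebkha import RectWindow
from nebkha.synthetic import LognormalMixture


@pytest.fixture
def square_window():
    return RectWindow(0.0, 0.0, 100.0, 100.0)


@pytest.fixture
def point_sizes():
    """Effectively zero-diameter discs (the classical point-process limit)."""
    return LognormalMixture((np.log(1e-9),), (0.01,), (1.0,))


@pytest.fixture
def small_sizes():
    """Sub-decimeter discs: negligible hard-core interaction at low density."""
    return LognormalMixture((np.log(0.05),), (0.1,), (1.0,))
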