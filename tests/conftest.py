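import math

import numpy as np
import pytest

from corrsubpop.preprocessing import VariablePair


def naive_pearson(x, y) -> float:
    """Independent two-pass Pearson oracle (no library call, no raw sums)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    denom = math.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0:
        return math.nan
    return float((dx * dy).sum() / denom)


def make_pair(x, y, ids=None, x_name="X", y_name="Y") -> VariablePair:
    x = np.asarray(x, dtype=float)
    if ids is None:
        width = max(2, len(str(max(len(x) - 1, 1))))
        ids = tuple(f"s{i:0{width}d}" for i in range(len(x)))
    return VariablePair(x_name, y_name, tuple(ids), x, np.asarray(y, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20160)


@pytest.fixture
def collinear_pair():
    """Ten points exactly on y = 2x + 1."""
    x = np.arange(10.0)
    return make_pair(x, 2 * x + 1)
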