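import numpy as np
import pytest

from xhwtest import GenotypeCounts


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_counts(rng, max_cell=40, n=1):
    """Random small count vectors with at least one male and one female."""
    out = []
    while len(out) < n:
        cells = rng.integers(0, max_cell + 1, size=5)
        c = GenotypeCounts(*map(int, cells))
        if c.Nm >= 1 and c.Nf >= 1:
            out.append(c)
    return out if n > 1 else out[0]
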