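import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def expand_2x2(a: int, b: int, c: int, d: int):
    """Rows for a 2x2 table: a exposed cases, b exposed controls,
    c unexposed cases, d unexposed controls."""
    design, outcome = [], []
    for exposed, case, count in ((1, 1, a), (1, 0, b), (0, 1, c), (0, 0, d)):
        design += [[1.0, float(exposed)]] * count
        outcome += [float(case)] * count
    return np.array(design), np.array(outcome)
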