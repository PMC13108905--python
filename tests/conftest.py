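import numpy as np
import pytest

from dkosim import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_config():
    """Three genes (negative / wild-type / control), two guides per gene,
    100x coverage: 6 SKO + 12 DKO constructs, library size 1800."""
    return SimConfig(
        n=3,
        n_guides=2,
        coverage=100,
        pct_gi=0.0,
        pct_neg=1 / 3,
        pct_pos=0.0,
        pct_wt=1 / 3,
        pct_ctrl=1 / 3,
        seed=7,
    )


@pytest.fixture
def small_config():
    """A 12-gene screen small enough for fast end-to-end runs."""
    return SimConfig(
        n=12,
        n_guides=2,
        coverage=50,
        pct_gi=0.2,
        pct_neg=0.25,
        pct_pos=1 / 12,
        pct_wt=7 / 12,
        pct_ctrl=1 / 12,
        seed=99,
    )
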