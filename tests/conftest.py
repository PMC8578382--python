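import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_level_trace(levels, frames_per=50, noise=40.0, seed=0):
    """Piecewise-constant trace with Gaussian noise, one chunk per level."""
    r = np.random.default_rng(seed)
    return np.concatenate([
        np.full(frames_per, float(lv)) + r.normal(0.0, noise, frames_per)
        for lv in levels
    ])
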