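import numpy as np
import pytest

from dgmean import DeltaGammaParams, sample_delta_gamma, summarize


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def typical_summary(rng):
    """Summary of one moderate zero-inflated gamma sample (n=60, delta=0.3)."""
    params = DeltaGammaParams(alpha=4.0, beta=1.5, delta=0.3)
    return summarize(sample_delta_gamma(params, 60, rng))


def make_sample(alpha, beta, delta, n, seed):
    params = DeltaGammaParams(alpha=alpha, beta=beta, delta=delta)
    return sample_delta_gamma(params, n, np.random.default_rng(seed))
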