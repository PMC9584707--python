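import numpy as np
import pytest

from mmdisten import EntropyConfig, MultichannelSignal


@pytest.fixture
def default_cfg() -> EntropyConfig:
    return EntropyConfig()


def random_signal(rng: np.random.Generator, c: int, n: int) -> MultichannelSignal:
    """A random multichannel test signal with correlated channels."""
    base = rng.standard_normal(n)
    data = np.stack([base * rng.uniform(0.5, 1.5) + 0.3 * rng.standard_normal(n) for _ in range(c)])
    return MultichannelSignal(data=data)
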