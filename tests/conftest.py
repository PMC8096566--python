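import numpy as np
import pytest

import breakcurve as bc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_dataset():
    """Three hand-written breakthrough records."""
    records = [
        bc.BreakthroughRecord(c0=8.0, h0=7.0, u=80.0, t=0.0, ratio=0.02),
        bc.BreakthroughRecord(c0=8.0, h0=7.0, u=80.0, t=60.0, ratio=0.55),
        bc.BreakthroughRecord(c0=24.0, h0=11.0, u=160.0, t=120.0, ratio=0.97),
    ]
    return bc.Dataset.from_records(records)


@pytest.fixture
def synthetic_dataset():
    """Default 204-record synthetic grid, mild noise, fixed seed."""
    return bc.generate(bc.SyntheticConfig(seed=7))


@pytest.fixture
def noiseless_dataset():
    return bc.generate(bc.SyntheticConfig(noise_sd=0.0, seed=0))
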