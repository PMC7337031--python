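"""Shared synthetic-study fixtures.

Session-scoped because the end-to-end fixtures (100 sites x 35 years of daily
SST) are the dominant cost; every test reads, none mutates.
"""

import numpy as np
import pytest

import reefcast as rc
from reefcast.synthetic import TruthConfig


@pytest.fixture(scope="session")
def bench_noise_free():
    """Default-shape study (100 sites, 1982-2016) with SST noise off:
    labels are an exact deterministic function of theta_true = 5.4."""
    return rc.simulate_dataset(seed=7, noise_free=True)


@pytest.fixture(scope="session")
def bench_noisy():
    """Default-shape study with red daily SST noise on."""
    return rc.simulate_dataset(seed=7)


@pytest.fixture(scope="session")
def bench_gate():
    """El Niño-gated truth on a longer ENSO record (60 sites, 1952-2016):
    events need annual-max Niño >= 0.8 on top of DHW >= 5.4."""
    return rc.simulate_dataset(
        n_sites=60,
        years=(1952, 2016),
        truth=TruthConfig(nino_gate=0.8),
        seed=7,
        baseline=(1952, 1982),
    )


@pytest.fixture(scope="session")
def random_tables():
    """1,000 uniformly random contingency tables with n = 3,500 each."""
    return rc.gen_contingency_tables(1000, 3500, seed=11)
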