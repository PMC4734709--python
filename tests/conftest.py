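import numpy as np
import pytest

from ampliseq.demux import demultiplex
from ampliseq.simulate import SimConfig, simulate_run


@pytest.fixture(scope="session")
def noise_free_run():
    """Small error-free simulated run shared across stage tests."""
    config = SimConfig(
        n_samples=4,
        n_targets=3,
        depth_mean=50,
        depth_dispersion=0,
        error_rate=0.0,
        barcode_error_rate=0.0,
        target_len_range=(300, 420),
        seed=20_240_101,
    )
    return simulate_run(config)


@pytest.fixture(scope="session")
def noise_free_pools(noise_free_run):
    pools, report = demultiplex(
        noise_free_run.reads,
        noise_free_run.barcodes,
        noise_free_run.primers,
        noise_free_run.samples,
    )
    return pools, report


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
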