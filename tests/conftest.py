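import pytest

from amgkit.synthetic_community import SimConfig, simulate_community


@pytest.fixture(scope="session")
def noise_free_config() -> SimConfig:
    return SimConfig(
        seed=11,
        n_phages=5,
        n_hosts=3,
        phage_len_range=(5_000, 12_000),
        host_len_range=(10_000, 18_000),
        coverage_noise=0.0,
        n_samples=2,
    )


@pytest.fixture(scope="session")
def community(noise_free_config):
    return simulate_community(noise_free_config)
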