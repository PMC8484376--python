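import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import poolcross as pc

settings.register_profile(
    "default", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> pc.CrossConfig:
    """Two-chromosome backcross with the causal locus near one
    chromosome end and a linked modifier on the other chromosome."""
    return pc.CrossConfig(
        chromosomes=[pc.Chromosome("chr1", 8_000_000),
                     pc.Chromosome("chr11", 4_000_000)],
        causal_locus=("chr11", 3_500_000),
        modifier_locus=("chr1", 4_000_000),
        n_backcross=200,
        variant_spacing_bp=5_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pedigree(small_config) -> pc.Pedigree:
    return pc.simulate_cross(small_config)


@pytest.fixture(scope="session")
def small_counts(small_pedigree):
    pools = [pc.PoolSpec("CAR", pc.carrier_at(), coverage=45),
             pc.PoolSpec("NON", pc.carrier_at(carrier=False), coverage=45)]
    return pc.simulate_pool_reads(small_pedigree, pools, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
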