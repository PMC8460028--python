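import pytest

from aneuscan import (
    NoiseModel,
    default_genome,
    pool_profiles,
    simulate_depth,
    simulate_tetrads,
)


def simulate_pools(genome, tetrad_set, seed, coverage=100.0, dispersion=50.0):
    """Resistant and sensitive pool profiles for one segregation replicate.

    Spore noise seeds are 10_000 + 100*seed + spore index, with the
    sensitive pool offset by 50 (declared scheme; distinct seeds for pools
    of up to 50 spores, always far below 2**31).
    """
    res, sen = simulate_tetrads(tetrad_set, NoiseModel(coverage, dispersion, seed))
    base = 10_000 + 100 * seed
    pool_r = pool_profiles(
        [simulate_depth(genome, k, NoiseModel(coverage, dispersion, base + i))
         for i, k in enumerate(res)]
    )
    pool_s = pool_profiles(
        [simulate_depth(genome, k, NoiseModel(coverage, dispersion, base + 50 + i))
         for i, k in enumerate(sen)]
    )
    return pool_r, pool_s


@pytest.fixture(scope="session")
def genome():
    return default_genome()


@pytest.fixture()
def noise():
    """Default noise at ~100-fold coverage, fixed seed."""
    return NoiseModel(mean_coverage=100.0, dispersion=50.0, seed=0)
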