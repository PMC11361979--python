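import pytest
from hypothesis import settings

from sdrscan.simulate import SimulationConfig, simulate_pools

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def small_lengths():
    """A scaled-down genome: 6 chromosomes of 2 Mb."""
    return {f"LG{i:02d}": 2_000_000 for i in range(1, 7)}


@pytest.fixture(scope="session")
def xy_dataset(small_lengths):
    """One XY-system dataset at study defaults (pools 23/26, 100x,
    400-kb SDR with 30% fully linked sites) on the scaled-down genome."""
    cfg = SimulationConfig(
        seed=1,
        chrom_lengths=small_lengths,
        sdr_chrom="LG05",
        sdr_interval=(800_000, 1_200_000),
    )
    sites, truth = simulate_pools(cfg)
    return cfg, sites, truth
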