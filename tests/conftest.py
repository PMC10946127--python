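import numpy as np
import pytest

from landgen.panel import HaplotypePanel
from landgen.sim import SimConfig, simulate_haplotypes, simulate_metadata


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale design: 1 gradient x 2 agroecologies, 2 pops each."""
    return SimConfig(
        n_gradients=2,
        agroecologies=("lowland", "highland"),
        pops_per_cell=1,
        n_extra_pops=0,
        samples_per_pop=20,
        n_chromosomes=2,
        chrom_length=2_000_000,
        n_snps=800,
        fst_level=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_frame(small_config):
    return simulate_metadata(small_config)


@pytest.fixture(scope="session")
def small_panel(small_config, small_frame):
    return simulate_haplotypes(small_config, small_frame)


def toy_panel(haps, positions=None, chrom=None, sample_prefix="s", missing=None):
    """Build a small panel from an explicit (n_hap, m) 0/1 matrix."""
    haps = np.asarray(haps, dtype=np.uint8)
    n_hap, m = haps.shape
    assert n_hap % 2 == 0
    positions = np.arange(1, m + 1) * 100 if positions is None else np.asarray(positions)
    chrom = np.repeat("1", m) if chrom is None else np.asarray(chrom, dtype=object)
    return HaplotypePanel(
        chrom=chrom,
        pos=positions,
        ref=np.repeat("A", m),
        alt=np.repeat("G", m),
        haplotypes=haps,
        sample_ids=[f"{sample_prefix}{i}" for i in range(n_hap // 2)],
        missing=missing,
    )
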