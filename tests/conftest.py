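import numpy as np
import pytest

from polyadmix.ioformats import Fragment, FragmentSet
from polyadmix.simdata import SimConfig, simulate_founders


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A small, fast simulation regime shared across module tests."""
    return SimConfig(
        seed=42,
        n_chrom=1,
        chrom_length=200_000,
        n_sites_per_chrom=400,
        fragment_count=220,
        fragment_length_mean=15_000,
        loh_tract_rate=0.0,
    )


@pytest.fixture(scope="session")
def small_pools(small_cfg):
    return simulate_founders(small_cfg)


def random_phasing_instance(rng, n_reads=None, n_sites=None, n_haps=None):
    """A noiseless small phasing instance: reads sampled from 2-4 haplotypes.

    Returns (FragmentSet, truth haplotype matrix).
    """
    n_sites = n_sites or int(rng.integers(6, 9))
    n_haps = n_haps or int(rng.integers(2, 5))
    n_reads = n_reads or int(rng.integers(6, 9))
    haps = rng.integers(0, 2, size=(n_haps, n_sites))
    frags = []
    for i in range(n_reads):
        start = int(rng.integers(0, n_sites - 1))
        length = int(rng.integers(2, n_sites - start + 1))
        h = int(rng.integers(0, n_haps))
        idx = np.arange(start, start + length)
        frags.append(Fragment(f"r{i:02d}", idx, haps[h, idx]))
    return FragmentSet(frags), haps
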