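import numpy as np
import pytest

from tetrasig.io import SequenceRecord
from tetrasig.simulate import SimulationConfig, simulate_polyploid_genome


@pytest.fixture(scope="session")
def small_auto_genome():
    """2 groups x 4 haplotypes x 20 kb auto-polyploid genome (session-cached)."""
    cfg = SimulationConfig(mode="auto", n_groups=2, chrom_len=20_000,
                           repeat_len=200, repeat_copies=40, d_hap=0.005, seed=5)
    genome, truth = simulate_polyploid_genome(cfg)
    return genome, truth, cfg


@pytest.fixture(scope="session")
def small_allo_genome():
    cfg = SimulationConfig(mode="allo", n_groups=2, chrom_len=20_000,
                           repeat_len=200, repeat_copies=40,
                           d_hap=0.005, d_sub=0.05, seed=6)
    genome, truth = simulate_polyploid_genome(cfg)
    return genome, truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_records(rng, n=3, length=1000, prefix="chr"):
    bases = np.array(list("ACGT"))
    return [
        SequenceRecord(f"{prefix}{i+1}", "".join(bases[rng.integers(0, 4, size=length)]))
        for i in range(n)
    ]
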