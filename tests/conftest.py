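import numpy as np
import pytest

from tricomp.hic_io import BinGrid
from tricomp.synthetic_data import SimulationConfig


@pytest.fixture
def grid10():
    """Ten 100-kb bins on one chromosome."""
    return BinGrid({"chr1": 1_000_000}, 100_000)


@pytest.fixture
def grid_two_chrom():
    return BinGrid({"chr1": 1_000_000, "chr2": 600_000}, 100_000)


@pytest.fixture
def small_sim_cfg():
    """Single 25-Mb chromosome: fast matrix simulations (250 bins)."""
    return SimulationConfig(chromosome_sizes={"chr1": 25_000_000})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
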