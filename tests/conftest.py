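import logging

import numpy as np
import pytest

from ulpcna import simulate as sim
from ulpcna.bins_io import BinGrid, build_bin_grid

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def small_grid() -> BinGrid:
    """A compact multi-chromosome grid (including chr19/chrX/chrY analogues)
    for fast unit tests; ~520 bins."""
    sizes = {
        "chr1": 120_000_000,
        "chr2": 100_000_000,
        "chr3": 80_000_000,
        "chr4": 60_000_000,
        "chr19": 40_000_000,
        "chrX": 80_000_000,
        "chrY": 40_000_000,
    }
    return build_bin_grid(sizes, 1_000_000)


@pytest.fixture(scope="session")
def hg19_grid() -> BinGrid:
    return sim.autosome_grid()


@pytest.fixture(scope="session")
def donor_reference(hg19_grid):
    """The default simulated 27-donor reference panel (shared: expensive)."""
    return sim.donor_panel(hg19_grid)
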