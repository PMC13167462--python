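import numpy as np
import pytest

from hazex import AreaWeights, Grid
from hazex import synthetic as syn


@pytest.fixture(scope="session")
def small_grid() -> Grid:
    """8x10 grid with a seeded blobby land mask (has both land and ocean)."""
    mask = syn.generate_land_mask(8, 10, seed=11, land_fraction=0.6)
    return Grid.regular(8, 10, 0.5, land_mask=mask)


@pytest.fixture(scope="session")
def small_areas(small_grid) -> AreaWeights:
    return AreaWeights.for_grid(small_grid)


@pytest.fixture(scope="session")
def small_control(small_grid):
    """40-year control run on the small grid, all variables."""
    return syn.generate_control(small_grid, 40, seed=101)


@pytest.fixture(scope="session")
def small_summaries(small_control):
    from hazex import summarize_control

    return summarize_control(small_control)
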