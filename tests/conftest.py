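import numpy as np
import pytest

import spore


def random_landcover(seed, max_side=50, n_classes=5, nodata_frac=0.1, cell_size=30.0):
    """Random categorical grid with a sprinkling of NoData cells."""
    rng = np.random.default_rng(seed)
    rows = int(rng.integers(3, max_side + 1))
    cols = int(rng.integers(3, max_side + 1))
    codes = rng.integers(0, n_classes, size=(rows, cols)).astype(np.int32)
    codes[rng.random((rows, cols)) < nodata_frac] = spore.NODATA_CODE
    return spore.LandcoverGrid(codes, cell_size)


@pytest.fixture(scope="session")
def guam_scenario():
    return spore.guam_like_scenario(seed=7)


@pytest.fixture(scope="session")
def guam_layers(guam_scenario):
    """All four score layers for the island scenario, computed once."""
    grid, table, profile = guam_scenario
    prio = spore.priority_score(grid, table)
    suit = spore.habitat_suitability(grid, profile)
    fs = spore.function_score(grid, table, profile)
    rs = spore.rewilding_score(fs, suit, profile, grid)
    return {"grid": grid, "table": table, "profile": profile,
            "priority": prio, "suitability": suit, "function": fs, "rewilding": rs}
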