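import numpy as np
import pandas as pd
import pytest

from maxniche import Grid, fit_maxent, sample_background, valid_mask
from maxniche import synthetic


@pytest.fixture(scope="session")
def small_stack():
    """40x40, 4 moderately smooth layers, one engineered collinear pair."""
    corr = np.eye(4)
    corr[0, 3] = corr[3, 0] = 0.9
    return synthetic.simulate_bioclim_stack((40, 40), n_layers=4, corr_target=corr,
                                            smoothing=3.0, seed=7)


@pytest.fixture(scope="session")
def small_niche(small_stack):
    return synthetic.make_virtual_niche(small_stack, {"Bio1": 6.0, "Bio3": -4.0})


@pytest.fixture(scope="session")
def small_fit(small_stack, small_niche):
    """A fitted model plus its presence/background matrices."""
    occ = synthetic.sample_presences(small_niche, n=150, dup_rate=0.0, seed=8)
    mask = valid_mask(small_stack)
    bg = sample_background(mask, 800, seed=9)
    B = pd.DataFrame(small_stack.values_at(bg.cells), columns=small_stack.codes)
    cells = np.asarray([c for c in occ.cells_on(mask) if c is not None])
    P = pd.DataFrame(small_stack.values_at(cells), columns=small_stack.codes)
    model = fit_maxent(P, B, feature_classes={"L", "Q"}, max_iter=1000)
    return model, P, B


@pytest.fixture()
def tiny_grid():
    """3x3 grid with one nodata cell, 0.5-degree cells."""
    vals = np.array([[1.0, 2.0, 3.0], [4.0, -9999.0, 6.0], [7.0, 8.0, 9.0]])
    return Grid(vals, (10.0, 45.0, 0.5), nodata=-9999.0)
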