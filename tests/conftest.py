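import numpy as np
import pytest

from paleoniche import synth
from paleoniche.grid import GridSpec, rasterize_presences
from paleoniche import niche


@pytest.fixture(scope="session")
def cfg():
    return synth.SimConfig(seed=11)


@pytest.fixture(scope="session")
def landscape(cfg):
    """50x50 all-land grid, 10 drifting slices, with true suitability."""
    stack, truth = synth.gen_landscape_stack(cfg)
    return stack, truth


@pytest.fixture(scope="session")
def small_grid():
    """10x10 all-land 0.1-degree grid near the equator."""
    return GridSpec(lon_min=10.0, lon_max=11.0, lat_min=-0.5, lat_max=0.5,
                    cell_size=0.1, land_mask=np.ones((10, 10), dtype=bool))


@pytest.fixture(scope="session")
def fitted_model(cfg, landscape):
    """A maxent-like model fitted on camps drawn from the true suitability."""
    stack, truth = landscape
    camps = synth.gen_camps(truth[0], 120, cfg.b_true, seed=21)
    pres = rasterize_presences(camps, stack.grid, buffer_km=20)
    model = niche.fit_enm(pres, stack.slice(0), background_n=800, seed=22)
    return model, pres
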