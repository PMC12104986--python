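"""Shared fixtures: small synthetic landscapes generated at test time."""

import numpy as np
import pytest

from maxsdm import synth
from maxsdm.raster import RasterGrid


@pytest.fixture(scope="session")
def grid100() -> RasterGrid:
    return RasterGrid(np.zeros((100, 100)), x0=0.0, y0=100_000.0,
                      dx=1000.0, dy=1000.0, crs="EPSG:32632")


@pytest.fixture(scope="session")
def stack2(grid100):
    """Two independent smooth layers plus a 4-class soil layer."""
    return synth.generate_env_stack(
        grid100, n_continuous=2, target_corr=np.eye(2), n_classes=4,
        smoothness=5.0, seed=11, names=["bio15", "bio4"],
        means=[45.0, 635.0], sds=[12.0, 80.0])


@pytest.fixture(scope="session")
def truth2(stack2):
    """Unimodal two-variable truth with soil preferences."""
    return synth.true_suitability(
        stack2, synth.default_truth_responses(),
        intercept=synth.DEFAULT_TRUTH_INTERCEPT)


@pytest.fixture(scope="session")
def presences2(truth2):
    return synth.sample_presences(truth2, n=400, seed=12)
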