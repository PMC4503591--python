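import numpy as np
import pytest

from nichegen.grids import GridSpec, RasterStack
from nichegen.synthetic import (
    NicheResponse,
    PredictorSpec,
    VirtualNiche,
    make_env_grids,
    virtual_suitability,
    sample_occurrences,
)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(west=-10.0, south=40.0, resolution=1.0, nx=10, ny=10)


@pytest.fixture(scope="session")
def env_stack():
    """60x40 environmental stack: two latitudinally structured predictors
    (temperature-like), two pure-noise layers."""
    specs = [
        PredictorSpec("sst", slope=-0.5, noise_sd=0.6, smoothing_length=2),
        PredictorSpec("airt", slope=-0.7, noise_sd=0.8, smoothing_length=2),
        PredictorSpec("noise1", slope=0.0, noise_sd=1.0, smoothing_length=2),
        PredictorSpec("noise2", slope=0.0, noise_sd=1.0, smoothing_length=2),
    ]
    return make_env_grids((-30, 30, 30, 70), 1.0, specs, seed=11)


@pytest.fixture(scope="session")
def cold_limited_niche():
    """A species limited by cold conditions polewards: suitability peaks at
    intermediate temperature, so uniform warming moves the band north."""
    return VirtualNiche(
        {
            "sst": NicheResponse(optimum=-25.0, tolerance=3.0),
            "airt": NicheResponse(optimum=-35.0, tolerance=4.0),
        },
        truth_threshold=0.3,
    )


@pytest.fixture(scope="session")
def truth_map(env_stack, cold_limited_niche):
    return virtual_suitability(env_stack, cold_limited_niche)


@pytest.fixture(scope="session")
def occurrences(truth_map, env_stack):
    return sample_occurrences(truth_map, env_stack.grid, 150, seed=7,
                              truth_threshold=0.3)


@pytest.fixture(scope="session")
def constant_stack(small_grid):
    return RasterStack(
        small_grid,
        {"a": np.full(small_grid.shape, 2.0), "b": np.full(small_grid.shape, 5.0)},
    )
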