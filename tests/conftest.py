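import numpy as np
import pytest

from fluosif import (
    SimConfig,
    compose_radiance,
    instrument_model,
    make_irradiance,
    make_reflectance,
    make_sif,
)


@pytest.fixture(scope="session")
def config():
    return SimConfig()


@pytest.fixture(scope="session")
def hr_grid(config):
    return config.grid_hr()


@pytest.fixture(scope="session")
def truth_grid():
    """Fine grid with margin, for honest line-spread convolution."""
    return np.arange(728.0, 782.001, 0.005)


def build_scene(
    grid,
    config=None,
    r_kind="constant",
    r_params=None,
    sif_kind="gaussian",
    magnitude=1.5,
    sif_params=None,
):
    """Truth E, R, SIF, L directly on ``grid`` (no instrument effects)."""
    config = config or SimConfig()
    e = make_irradiance(grid, config)
    r = make_reflectance(grid, r_kind, r_params or {"value": 0.42})
    s = make_sif(grid, sif_kind, magnitude, sif_params or {"peak": 740.0, "width": 20.0})
    return e, r, s, compose_radiance(e, r, s)


@pytest.fixture(scope="session")
def observed_scene(config, hr_grid, truth_grid):
    """Noiseless instrument-sampled flat-R scene with known SIF760 = 1.5."""
    e_t, r_t, s_t, l_t = build_scene(truth_grid, config)
    e = instrument_model(e_t, config.fwhm_hr, hr_grid, 0.0, 0.0)
    l = instrument_model(l_t, config.fwhm_hr, hr_grid, 0.0, 0.0)
    return e, l
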