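import numpy as np
import pytest

from octskin.phantom import PhantomParams, make_volume


@pytest.fixture
def flat_params():
    """Noise-free, perfectly flat phantom: epidermis rows 10-89 everywhere."""
    return PhantomParams(
        height=128,
        width=32,
        surface_depth_px=10,
        surface_amplitude_px=0.0,
        epi_thickness_mean_px=80,
        epi_thickness_var_px=0.0,
        epi_thickness_max_px=None,
        speckle_shape=0.0,
        noise_sigma=0.0,
        seed=0,
    )


@pytest.fixture
def small_volume():
    """A small noisy source-domain volume with truth."""
    params = PhantomParams(height=64, width=48, surface_depth_px=14, seed=7)
    return make_volume(params, n_bscans=3) + (params,)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
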