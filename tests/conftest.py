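import numpy as np
import pytest

from ocquant.synth.cochlea import CochleaSimParams, generate_cochlea_volume
from ocquant.synth.counts import CountsSimParams, simulate_counts
from ocquant.synth.lso import GradientSimParams, generate_lso_image


@pytest.fixture(scope="session")
def clean_lso():
    """Noise-free LSO section with flat neuropil: exact ground truth."""
    params = GradientSimParams(
        rng_seed=11, n_cells=60, noise_sd=0.0, pixel_noise_sd=0.0,
        neuropil_texture=0.0, image_shape=(384, 384),
    )
    return params, generate_lso_image(params)


@pytest.fixture(scope="session")
def decoy_lso():
    """Section with decoy objects outside the polygon and sliver shapes."""
    params = GradientSimParams(
        rng_seed=5, n_cells=30, noise_sd=0.02, pixel_noise_sd=0.01,
        n_decoys_outside=4, n_decoys_misshapen=3, image_shape=(384, 384),
    )
    return params, generate_lso_image(params)


@pytest.fixture(scope="session")
def clean_cochlea():
    """Noise-free cochlear volume with planted puncta and flags."""
    params = CochleaSimParams(rng_seed=21, noise_sd=0.0)
    return params, generate_cochlea_volume(params)


@pytest.fixture(scope="session")
def toy_counts():
    """Small count matrix with planted QC failures."""
    params = CountsSimParams(rng_seed=31)
    return params, simulate_counts(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
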