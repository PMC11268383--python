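import numpy as np
import pytest

from hsipath.cube import TRANSMITTANCE, Hypercube
from hsipath.synthetic import SceneConfig, make_stain_basis, render_patch


@pytest.fixture
def wl8():
    return np.linspace(467.0, 721.0, 8)


@pytest.fixture
def wl84():
    return np.linspace(467.0, 721.0, 84)


@pytest.fixture
def small_cube(wl8):
    rng = np.random.default_rng(7)
    data = np.clip(rng.random((16, 16, 8)), 0.0, 1.0)
    return Hypercube(data, wl8, TRANSMITTANCE)


@pytest.fixture
def rendered_cancer():
    cfg = SceneConfig(patch_px=48, n_bands=8, noise_sd=0.0, seed=3, tissue_class="cancer")
    basis = make_stain_basis(cfg.wavelengths)
    cube, ab = render_patch(cfg, basis)
    return cube, ab, basis
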