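import numpy as np
import pytest

from spark3d.simulate import SimulationConfig


@pytest.fixture
def small_sim_config():
    """Desk-scale scene: same voxel geometry as the defaults, small grid."""
    return SimulationConfig(
        grid_shape=(16, 192, 192),
        nucleus_semiaxes=(0.5, 3.0, 3.4),
        n_events=12,
        seed=1,
    )


def gaussian_blob(shape, centre_vox, sigma_vox, amplitude=100.0, reach=5.0):
    """Noise-free isotropic Gaussian blob with compact support (exact zeros
    beyond ``reach`` sigma), for translation-exact segmentation tests."""
    out = np.zeros(shape)
    c = np.asarray(centre_vox, float)
    lo = np.maximum(np.floor(c - reach * sigma_vox).astype(int), 0)
    hi = np.minimum(np.ceil(c + reach * sigma_vox).astype(int) + 1, shape)
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                        indexing="ij")
    r2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    out[tuple(slice(l, h) for l, h in zip(lo, hi))] += (
        amplitude * np.exp(-r2 / (2.0 * sigma_vox ** 2))
    )
    return out
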