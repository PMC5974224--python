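import numpy as np
import pytest

from gliapipe import SceneSpec, generate_stack


@pytest.fixture(scope="session")
def clean_scene():
    """A mixed noise-free, PSF-free scene: 5 microglia, 3 astrocytes,
    6 other nuclei, all in the 1000-1500 voxel range."""
    spec = SceneSpec(seed=11, noise=(None, None), psf_sigma=None)
    stack, truth = generate_stack(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def noisy_scene():
    """Same layout with the default Poisson + Gaussian noise, PSF off."""
    spec = SceneSpec(seed=11, psf_sigma=None)
    stack, truth = generate_stack(spec)
    return spec, stack, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def brute_force_dilate(mask: np.ndarray, radius: float) -> np.ndarray:
    """O(N*M) Euclidean-ball dilation oracle on the voxel grid."""
    pts = np.argwhere(mask)
    out = np.zeros_like(mask, dtype=bool)
    if pts.size == 0:
        return out
    for idx in np.ndindex(mask.shape):
        d2 = ((pts - np.array(idx)) ** 2).sum(axis=1)
        if (d2 <= radius * radius).any():
            out[idx] = True
    return out
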