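import numpy as np
import pytest

from tfa.model import ImageDataset, SourceSet, build_basis_matrix
from tfa.synthetic import generate_tfa_dataset, make_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid2d():
    return make_grid((8, 8))


@pytest.fixture
def grid3d():
    return make_grid((6, 6, 4))


@pytest.fixture
def small_bundle(grid3d):
    """3 separated sources, 40 images, moderate noise."""
    return generate_tfa_dataset(3, 40, grid3d, snr=5.0, seed=7, separated=True)


@pytest.fixture
def tiny_dataset(grid2d, rng):
    """Unstructured dataset for shape/contract tests."""
    acts = rng.standard_normal((5, grid2d.shape[0]))
    return ImageDataset(activations=acts, coords=grid2d)


@pytest.fixture
def planted_rbf_dataset(grid2d):
    """Images that are exact multiples of a single voxel-centered RBF."""
    sources = SourceSet([[3.0, 4.0]], [1.2])
    basis = build_basis_matrix(sources, grid2d)
    weights = np.linspace(0.5, 2.0, 6)[:, None]
    data = ImageDataset(activations=weights @ basis, coords=grid2d)
    return sources, weights, data
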