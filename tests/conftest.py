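import numpy as np
import pytest

from mitopipe import synthdata as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_tiles():
    """A dozen multi-nucleus 32x32 tiles for quick segmentation tests."""
    spec = sd.TileSpec(width=32, height=32, n_mitotic=1, n_nonmitotic=2,
                       nucleus_radius_range=(3.0, 5.0))
    return sd.generate_segmentation_tiles(12, spec, seed=7)


@pytest.fixture(scope="session")
def labeled_patches():
    """Single-nucleus 32x32 patches with binary labels (1 = mitotic)."""
    spec = sd.TileSpec(width=32, height=32, nucleus_radius_range=(4.0, 7.0))
    tiles, _ = sd.generate_dataset(20, 20, spec, seed=11)
    patches = np.stack([t.image for t in tiles]).astype(float)
    y = np.array([1 if t.label == sd.MITOTIC else 0 for t in tiles])
    return patches, y


@pytest.fixture(scope="session")
def separable_features():
    """Linearly separable feature matrix in [0, 1] with binary labels."""
    gen = np.random.default_rng(3)
    x = np.vstack([gen.uniform(0.0, 0.4, size=(30, 16)),
                   gen.uniform(0.6, 1.0, size=(30, 16))])
    y = np.array([0] * 30 + [1] * 30)
    return x, y
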