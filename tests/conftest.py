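import numpy as np
import pytest

import hsiclass as h


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_cube(rng):
    """6 x 5 x 8 random reflectance cube."""
    values = rng.uniform(0.0, 1.0, (6, 5, 8))
    wavelengths = np.linspace(400, 1000, 8)
    return h.HyperspectralCube(values, wavelengths)


@pytest.fixture(scope="session")
def tiny_scene():
    """A small separable scene shared by read-only tests."""
    cfg = h.default_config(height=40, width=40, n_bands=16,
                           unlabeled_fraction=0.5)
    return h.generate_scene(cfg, seed=7), cfg


def make_toy_patches(n_per_class=30, S=5, B=4, n_classes=3, noise=0.05,
                     seed=0):
    """Separable toy patch dataset: class c has mean level c."""
    rng = np.random.default_rng(seed)
    patches, labels, coords = [], [], []
    for c in range(1, n_classes + 1):
        block = c + noise * rng.standard_normal((n_per_class, S, S, B))
        patches.append(block.astype(np.float32))
        labels.extend([c] * n_per_class)
        coords.extend((c * 100 + i, i) for i in range(n_per_class))
    return h.PatchDataset(np.concatenate(patches),
                          np.array(labels, dtype=np.int64),
                          np.array(coords, dtype=np.int64), S, B)


@pytest.fixture()
def toy_patches():
    return make_toy_patches()


def fast_spec(B, S, n_classes=3, widths=(4, 8, 8, 8), a=1):
    """Smallest legal dual-branch spec; for contract tests, not learning."""
    return h.build_3d_rnet_o(widths=widths, a=a, stem_kernel=(1, 1, 1),
                             pool_window=(1, 1, 1), n_classes=n_classes,
                             default_input=(B, S, S))
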