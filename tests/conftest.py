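"""Shared fixtures: small synthetic datasets and an aligned shape library.

The expensive objects (library, feature table) are session-scoped so the
end-to-end and feature-table tests share one computation.
"""

import numpy as np
import pytest

import nucmorph as nm


@pytest.fixture(scope="session")
def library160():
    """80 normal + 80 HCC aligned library masks from a 100-per-class pool."""
    pool, _ = nm.generate_dataset(100, seed=42)
    return nm.library_from_patches(pool, n_per_class=80, seed=42)


@pytest.fixture(scope="session")
def dataset400():
    """200 nuclei per class, the default end-to-end study size."""
    patches, manifest = nm.generate_dataset(200, seed=7)
    return patches, manifest


@pytest.fixture(scope="session")
def table_ji_bf(dataset400, library160):
    """JI (160) + BF (220) feature table of the 400-nucleus dataset."""
    patches, _ = dataset400
    return nm.extract_features(patches, library=library160, metrics=("JI",),
                               include_boundary=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blob(rng, patch_size=100, aspect=(1.0, 2.0), eps=(0.0, 0.25),
                area=(600, 1600)):
    """One random star-shaped nucleus mask."""
    params = nm.ClassParams(area=area, aspect=aspect, epsilon=eps)
    model = nm.sample_model(params, "unknown", rng)
    return nm.generate_mask(model, patch_size=patch_size, seed=rng).mask


def rigid_scale_copy(mask, rng, canvas=220):
    """A randomly rotated, rescaled and shifted copy of ``mask``."""
    from skimage.transform import rescale, rotate

    ang = rng.uniform(0, 360)
    sc = rng.uniform(0.7, 1.4)
    img = rotate(mask.astype(float), ang, resize=True, order=1)
    img = rescale(img, sc, order=1)
    h, w = img.shape
    big = np.zeros((canvas, canvas))
    r0 = int(rng.integers(0, canvas - h))
    c0 = int(rng.integers(0, canvas - w))
    big[r0:r0 + h, c0:c0 + w] = img
    return big > 0.5


def center_crop(mask, size=100):
    h, w = mask.shape
    r = (h - size) // 2
    c = (w - size) // 2
    return mask[r:r + size, c:c + size]
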