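import numpy as np
import pytest

from upside import (CellPhenotypeSpec, CropCanonicalizer, VAEEncoder,
                    make_crop_dataset)


def two_class_phenotypes():
    """Round-small, weakly textured vs elongated-large, granulated."""
    return [
        CellPhenotypeSpec(class_id=0, area_mean=220, area_sd=20,
                          eccentricity_mean=0.2, eccentricity_sd=0.05,
                          edge_contrast=0.3, granule_density=0.0),
        CellPhenotypeSpec(class_id=1, area_mean=450, area_sd=35,
                          eccentricity_mean=0.75, eccentricity_sd=0.05,
                          edge_contrast=0.1, granule_density=0.06,
                          granule_darkness=0.3),
    ]


@pytest.fixture(scope="session")
def two_class_crops():
    crops, labels = make_crop_dataset(two_class_phenotypes(), 80, seed=1,
                                      patch_size=64)
    return crops, labels


@pytest.fixture(scope="session")
def canonical_two_class(two_class_crops):
    crops, labels = two_class_crops
    masks, textures = CropCanonicalizer().transform(crops)
    return masks, textures, labels


@pytest.fixture(scope="session")
def twin_vaes(canonical_two_class):
    """One trained shape VAE + texture VAE pair, shared across tests."""
    masks, textures, _ = canonical_two_class
    shape_vae = VAEEncoder(latent_dim=16, hidden=128, steps=700,
                           seed=0).fit(masks)
    texture_vae = VAEEncoder(latent_dim=16, hidden=128, steps=700,
                             seed=1).fit(textures)
    return shape_vae, texture_vae


@pytest.fixture(scope="session")
def blob_images():
    """Small toy images (shifted Gaussian bumps) for fast encoder tests."""
    rng = np.random.default_rng(0)
    yy, xx = np.mgrid[0:16, 0:16]
    imgs = np.empty((300, 16, 16))
    for i in range(300):
        cy, cx = rng.uniform(4, 12, 2)
        s = rng.uniform(1.5, 3.5)
        imgs[i] = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s * s))
    return imgs
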