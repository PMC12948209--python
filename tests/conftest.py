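import warnings

import numpy as np
import pytest

from vox3dmsi import FeatureAxis, PhantomSpec, SectionImage, generate_phantom


def small_spec(**kw) -> PhantomSpec:
    """A fast phantom: 200 µm spheroid -> 20 sections, ~36 px grid."""
    defaults = dict(
        spheroid_radius_um=200.0,
        n_clusters=5,
        cluster_class_mix=(1, 2, 2),
        cluster_radius_range_um=(18.0, 70.0),
        margin_px=8,
        seed=0,
    )
    defaults.update(kw)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def default_phantom():
    """One full-size biculture phantom shared across tests."""
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_spec(seed=5))


@pytest.fixture(scope="session")
def clean_small_phantom():
    """Noise-free, unperturbed, binary-voxel small phantom."""
    return generate_phantom(small_spec(
        seed=5, sigma_mult=0.0, sigma_add=0.0,
        perturb_translation_px=0.0, perturb_rotation_deg=0.0,
        landmark_texture=0.0, edge_width_px=0.0,
    ))


@pytest.fixture
def simple_axis():
    return FeatureAxis((100.0, 200.0, 300.0), tolerance_ppm=10.0)


def random_section(rng: np.random.Generator, height=6, width=7, n_features=3,
                   z_index=0) -> SectionImage:
    """Random section whose foreground touches every grid edge, so the
    imzML round trip (which crops to the spectra's bounding box) is the
    identity."""
    mask = rng.random((height, width)) < 0.6
    mask[0, 0] = mask[-1, -1] = mask[0, -1] = mask[-1, 0] = True
    inten = np.where(mask[..., None],
                     rng.gamma(2.0, 50.0, (height, width, n_features)), 0.0)
    return SectionImage(inten, mask, 20.0, 20.0, z_index)


@pytest.fixture(autouse=True)
def _silence_registration_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
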