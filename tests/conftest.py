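import numpy as np
import pytest

from rectseg.phantom import PhantomSpec, generate_phantom
from rectseg.preprocess import PreprocessConfig


def clean_spec(**overrides) -> PhantomSpec:
    """Noiseless, bias-free, undeformed 64x64 phantom spec used by the
    closed-form contracts."""
    base = dict(
        grid_shape=(64, 64, 4),
        voxel_spacing=(1.0, 1.0, 4.0),
        lumen_radius_range=(3.0, 5.0),
        wall_thickness_range=(2.5, 4.0),
        fat_ring_thickness_range=(4.0, 6.0),
        muscle_offset=24.0,
        muscle_radius=4.0,
        noise_sigma=0.0,
        bias_amplitude=0.0,
        deform_magnitude=0.0,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def noiseless_case():
    return generate_phantom(clean_spec(), seed=3)


@pytest.fixture(scope="session")
def noisy_case():
    return generate_phantom(
        clean_spec(noise_sigma=0.05, bias_amplitude=0.2, deform_magnitude=0.8), seed=4
    )


@pytest.fixture()
def small_pp_config():
    return PreprocessConfig(
        target_spacing=(1.0, 1.0, 4.0),
        bias_method="smooth_div",
        crop_fraction=1.0,
        net_input_size=64,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_blob_mask(rng, shape=(48, 48), n_blobs=2, r=(3, 9)) -> np.ndarray:
    """Random union of disks — generic test mask."""
    mask = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(r[1], shape[0] - r[1]), rng.uniform(r[1], shape[1] - r[1])
        rad = rng.uniform(*r)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 < rad**2
    return mask
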