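import numpy as np
import pytest

from chemotax import (
    PlateGeometry,
    SyntheticPlateSpec,
    build_region_map,
    generate_synthetic_plate,
)

# compact plates keep the suite fast; worm pixel scale is preserved
SMALL = dict(image_size=384, plate_radius=150.0, worm_area_px=60)


def small_spec(**kwargs) -> SyntheticPlateSpec:
    params = {**SMALL, **kwargs}
    return SyntheticPlateSpec(**params)


@pytest.fixture(scope="session")
def default_plate():
    """One default-noise plate with an uneven worm distribution."""
    spec = small_spec(worms_per_quadrant=(10, 3, 9, 4), seed=11)
    image, truth = generate_synthetic_plate(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def clean_plate():
    """A noise/blur/vignette-free plate: segmentation should be exact."""
    spec = small_spec(
        worms_per_quadrant=(8, 2, 7, 3),
        vignette_strength=0.0,
        noise_sd=0.0,
        blur_sigma=0.0,
        seed=5,
    )
    image, truth = generate_synthetic_plate(spec)
    return spec, image, truth


@pytest.fixture()
def centered_geometry():
    return PlateGeometry(center=(191.5, 191.5), radius=150.0)


@pytest.fixture()
def region_map(centered_geometry):
    return build_region_map(centered_geometry, (384, 384))
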