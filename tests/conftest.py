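import numpy as np
import pytest

from granulekit import ImageStack, label_objects, measure_objects, threshold_image
from granulekit.synthetic import GranuleFieldParams, generate_granule_image


@pytest.fixture(scope="session")
def sphere_field():
    """50 well-separated noise-free spheres with ground truth."""
    params = GranuleFieldParams(
        field_shape=(40, 300, 300),
        voxel_size_nm=(100.0, 50.0, 50.0),
        n_granules=50,
        diameter_mean_nm=400.0,
        diameter_sd_nm=60.0,
        min_separation_nm=2000.0,
        unit_intensity=1000.0,
        copies_distribution=("constant_concentration", 900.0),
        seed=7,
    )
    stack, truth = generate_granule_image(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def sphere_records(sphere_field):
    """Segmented + measured records of the sphere field.

    The half-maximum threshold puts the object boundary at the 50% fill
    contour, the unbiased voxelization of a hard sphere.
    """
    _, stack, truth = sphere_field
    mask = threshold_image(stack, method="fraction_of_max", fraction=0.5)
    labels = label_objects(mask)
    records = measure_objects(labels, stack)
    return stack, truth, labels, records


@pytest.fixture
def two_level_image():
    """Condensate-like two-phase image: inside 1000, outside 100."""
    img = np.full((60, 60), 100.0)
    img[15:30, 20:40] = 1000.0
    stack = ImageStack(img[np.newaxis], ["c"], (50.0, 50.0))
    return stack, img > 500
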