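import numpy as np
import pytest

from corneaquant import tem
from corneaquant.synthetic import FibrilFieldParams, generate_fibril_field


@pytest.fixture(scope="session")
def clean_field():
    """Noise-free mid-density field shared by segmentation-recovery tests."""
    params = FibrilFieldParams(
        target_density=40.0,
        diameter_mean_nm=32.0,
        diameter_sd_nm=5.0,
        field_width_px=1024,
        field_height_px=1024,
        pixel_size_nm=2.0,
        noise_sd=0.0,
        seed=11,
    )
    field, image = generate_fibril_field(params)
    return params, field, image


@pytest.fixture(scope="session")
def clean_detections(clean_field):
    params, field, image = clean_field
    seg = tem.SegmentationConfig()
    mask = tem.binarize_adaptive(image, seg)
    return tem.detect_fibrils(mask, params.pixel_size_nm, seg)


def truth_centroids_px(field, params):
    """Truth centers in detector (row, col) pixel coordinates."""
    return np.column_stack(
        [
            field.centers_nm[:, 1] / params.pixel_size_nm - 0.5,
            field.centers_nm[:, 0] / params.pixel_size_nm - 0.5,
        ]
    )
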