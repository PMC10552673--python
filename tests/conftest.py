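import numpy as np
import pytest

from myohisto.imgio import GrayImage
from myohisto.segmentation import SegmentationParams
from myohisto.thresholding import ThresholdConfig


def disk_image(shape, centers, radius):
    """Binary-valued GrayImage with bright disks at the given (row, col) centers."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = np.zeros(shape, dtype=bool)
    for cy, cx in centers:
        img |= (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    return GrayImage(img.astype(float))


@pytest.fixture
def two_disjoint_disks():
    """Two bright disks of diameter 20, far apart on a black background."""
    return disk_image((64, 128), [(32, 30), (32, 95)], radius=10)


@pytest.fixture
def two_overlapping_disks():
    """Two bright disks of diameter 20 whose centers are 15 px apart."""
    return disk_image((64, 96), [(32, 40), (32, 55)], radius=10)


@pytest.fixture
def manual_half():
    return ThresholdConfig(method="manual", manual_value=0.5)


@pytest.fixture
def disk_params(manual_half):
    return SegmentationParams(
        min_diameter=10, max_diameter=40, threshold=manual_half,
        declump=True, smoothing_sigma=2.0, min_seed_distance=5.0,
    )
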