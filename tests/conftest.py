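import numpy as np
import pytest

from curemetrics._cart import warmup
from curemetrics.imaging import extract_feature_table, FEATURE_NAMES
from curemetrics.synthetic import StorageProfile, generate_image_dataset


@pytest.fixture(scope="session", autouse=True)
def _jit_warmup():
    """Compile the jitted tree builder once, outside any timed assertion."""
    warmup()


@pytest.fixture(scope="session")
def day_pair_features():
    """Per-ROI feature table for day 1 vs day 16 under the default profile.

    8 slices x 8 ROIs per day: 64 observations per storage-day class.
    """
    profile = StorageProfile(days=(1, 16))
    images = generate_image_dataset(profile, seed=0)
    return extract_feature_table(images)


@pytest.fixture(scope="session")
def small_series_features():
    """Light three-day series (128 px images) for trend checks."""
    profile = StorageProfile(days=(1, 8, 16), slices_per_day=4, image_size=(128, 128))
    images = generate_image_dataset(profile, seed=1)
    return extract_feature_table(images, n_rois=4, roi_size=(48, 48))
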