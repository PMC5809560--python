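import numpy as np
import pytest

from shgtex.config import FeatureConfig
from shgtex.bof import extract_dataset_features
from shgtex.synthetic import TissueTextureParams, gen_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def bench2():
    """Full-size 2-class benchmark dataset (acceptance criterion scale)."""
    dataset, manifest = gen_dataset(40, ("Cartilage", "Bone"), seed=7, size=512)
    return dataset, manifest


@pytest.fixture(scope="session")
def bench2_features_g64(bench2):
    dataset, _ = bench2
    return extract_dataset_features(dataset, FeatureConfig(grid_step=64))


@pytest.fixture(scope="session")
def bench2_features_g32(bench2):
    dataset, _ = bench2
    return extract_dataset_features(dataset, FeatureConfig(grid_step=32))


@pytest.fixture(scope="session")
def bench3_hard():
    """3-class task with dominant within-class variation (codebook sensitivity)."""
    params_by_class = {
        "Fibrous": TissueTextureParams.fibrous(
            fiber_count=30, fiber_gain=40.0, fiber_width_px=1.3
        )
    }
    dataset, _ = gen_dataset(
        16,
        ("Hyaline", "Fibrous", "Bone"),
        seed=11,
        size=512,
        noise_range_rel=(0.5, 2.0),
        params_by_class=params_by_class,
    )
    return dataset, extract_dataset_features(dataset)


@pytest.fixture(scope="session")
def small_two_class():
    """Small, fast 2-class dataset for unit-level pipeline tests."""
    dataset, _ = gen_dataset(8, ("Cartilage", "Bone"), seed=3, size=256)
    return dataset
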