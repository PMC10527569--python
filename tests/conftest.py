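import numpy as np
import pytest

from dermfusion import FeatureFixtureSpec, ImageFixtureSpec, make_feature_dataset, make_hazy_images


@pytest.fixture(scope="session")
def small_imageset():
    """21 hazy lesion images (7 classes x 3) with known clean truth."""
    return make_hazy_images(ImageFixtureSpec(images_per_class=3, seed=1))


@pytest.fixture(scope="session")
def paired_dataset():
    """Feature table whose informative columns sit next to their duplicates."""
    spec = FeatureFixtureSpec(
        n_samples=140, n_classes=7, n_informative=5, n_noise=10, n_redundant=5,
        class_separation=6.0, layout="paired", seed=3,
    )
    return make_feature_dataset(spec)


@pytest.fixture(scope="session")
def separable_small():
    """d=8 separable table small enough for exhaustive subset search."""
    spec = FeatureFixtureSpec(
        n_samples=80, n_classes=4, n_informative=3, n_noise=5, n_redundant=0,
        class_separation=6.0, seed=11,
    )
    return make_feature_dataset(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
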