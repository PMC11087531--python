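import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def feature_table():
    """Default two-class table: 5 informative of 30 features, shift 2.0."""
    from qigwo.synthetic_data import FeatureTableSpec, make_feature_table

    return make_feature_table(FeatureTableSpec(seed=7))


@pytest.fixture(scope="session")
def tiny_corpus():
    """Small phantom corpus (6 normal / 3 benign / 3 malignant, 256 px)."""
    from qigwo.synthetic_data import PhantomSpec, make_mias_like_corpus

    spec = PhantomSpec(counts=(6, 3, 3), image_size=256, seed=21)
    images, annotation_text = make_mias_like_corpus(spec)
    return images, annotation_text
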