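import numpy as np
import pytest

import tissuegrid as tg


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """Small untrained 3-class classifier (16 px input) shared read-only."""
    cfg = tg.ModelConfig(n_classes=3, input_size=16, bilinear_m=8, bilinear_k=4)
    return tg.build_classifier(cfg, seed=0)


@pytest.fixture(scope="session")
def two_class_dataset():
    """Small, quickly learnable two-class texture set."""
    specs = tg.easy_preset()[:2]
    ds = tg.generate_patch_dataset(specs, 40, 32, seed=21)
    return tg.stratified_split(ds, 0.25, seed=21)
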