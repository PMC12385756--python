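import numpy as np
import pytest

from robustfood.config import RunConfig
from robustfood.data import generate_toy_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def toy_cfg():
    """Desk-scale run configuration shared by the heavier tests."""
    cfg = RunConfig()
    cfg.model.feature_channels = 16
    cfg.model.head_hidden = 0
    cfg.model.restore_channels = 8
    cfg.training.batch_size = 16
    cfg.training.lr0 = 0.02
    return cfg


@pytest.fixture(scope="session")
def toy_manifest_small(tmp_path_factory):
    """3 classes x 12 images at 32x32 - enough for shape/pipeline tests."""
    root = tmp_path_factory.mktemp("toyset_small")
    return generate_toy_dataset(3, 12, root, image_size=32, seed=11)
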