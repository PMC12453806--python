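import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from hmcformer.config import ModelConfig
from hmcformer.synthetic import CLASS_SPECS, generate_image


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def lesion_image():
    """A CIN2-style image: pale patch on pink cervix (fixture for the
    enhancement contrast checks)."""
    img, mask = generate_image(CLASS_SPECS["CIN2"], seed=42, size=128)
    return img, mask


def micro_config(num_classes: int = 3) -> ModelConfig:
    """Smallest legal model: fast unit-test instantiation."""
    return ModelConfig(embed_dim=8, transformer_depths=(2, 2, 2, 2),
                       cnn_depths=(1, 1, 1, 1), img_size=56, window_size=7,
                       drop_path=0.0, num_classes=num_classes)


@pytest.fixture(scope="session")
def micro_model():
    from hmcformer.model import build_model

    return build_model(micro_config(), seed=3)
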