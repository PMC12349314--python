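import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_rl_model():
    """A full-variant model with a 3-class head, shared across tests."""
    from citrusdet.model_zoo import ModelConfig, build_model
    return build_model(ModelConfig(variant="yolov8_rl", num_classes=3,
                                   input_size=128, seed=7))
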