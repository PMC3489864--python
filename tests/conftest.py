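import numpy as np
import pytest

from circadde.clock import build_per2_model, calibrate_per2_model
from circadde.cli import load_preset_model


@pytest.fixture(scope="session")
def per2_calibrated():
    """One-gene Per2 model calibrated to a 24 h rhythm at 8 h delay."""
    model, info = calibrate_per2_model()
    return model, info


@pytest.fixture(scope="session")
def liver_model():
    """The packaged fitted six-variable liver model."""
    return load_preset_model()


@pytest.fixture(scope="session")
def liver_cycle(liver_model):
    from circadde.clock import limit_cycle
    return limit_cycle(liver_model, t_end=480.0, step=0.05)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
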