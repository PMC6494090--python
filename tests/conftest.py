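import numpy as np
import pytest

from macula.simulate import PitParams, generate_eye


@pytest.fixture
def example_params() -> PitParams:
    """Reference DoG parameters used by the frozen-oracle tests."""
    return PitParams(base_um=280.0, a1_um=60.0, s1_mm=1.2, a2_um=120.0, s2_mm=0.45)


@pytest.fixture
def typical_params() -> PitParams:
    """Population-mean pit shape of the synthetic generator."""
    return PitParams(base_um=276.0, a1_um=48.0, s1_mm=0.92, a2_um=138.0, s2_mm=0.37)


@pytest.fixture
def noiseless_eye(typical_params):
    """Centred, noiseless synthetic eye at the device-assumed axial length."""
    return generate_eye(
        typical_params,
        axial_mm=24.46,
        grid_dim=128,
        noise_sd_um=0.0,
        rng=np.random.default_rng(0),
    )
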