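import numpy as np
import pytest

from speckleshock import (
    AcquisitionConfig,
    make_phantom,
    simulate_speckle_stack,
)


@pytest.fixture(scope="session")
def acq() -> AcquisitionConfig:
    return AcquisitionConfig()  # 5 ms exposure, 15 fps, 805 nm


@pytest.fixture(scope="session")
def dynamic_stack(acq):
    """tau_c = exposure (T/tau_c = 1), 64x64, 30 frames."""
    phantom = make_phantom("uniform", 0.005, (64, 64))
    return simulate_speckle_stack(phantom, acq, n_frames=30, seed=42)


@pytest.fixture(scope="session")
def static_frame():
    """One 512x512 static fully developed speckle frame (beta = 1)."""
    phantom = make_phantom("uniform", np.inf, (512, 512))
    stack = simulate_speckle_stack(phantom, n_frames=1, seed=7)
    return stack.frames[0]


@pytest.fixture(scope="session")
def two_region_stack(acq):
    """Left half fast (2 ms), right half slow (8 ms), 64x128, 30 frames."""
    phantom = make_phantom("two_region", (0.002, 0.008), (64, 128))
    return simulate_speckle_stack(phantom, acq, n_frames=30, seed=11)
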