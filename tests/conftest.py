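import numpy as np
import pytest

import aortaflow as af


@pytest.fixture(scope="session")
def straight_phantom():
    """Noise-free straight tube with swirl, 4 frames."""
    spec = af.PhantomSpec(
        geometry_kind="straight",
        geometry_params={"length": 80.0},
        lumen_radius=7.0,
        swirl_ratio=0.3,
        n_timeframes=4,
        snr=np.inf,
        seed=0,
    )
    data, gt = af.generate_phantom(spec)
    return spec, data, gt


@pytest.fixture(scope="session")
def aorta_phantom():
    """Default candy-cane phantom with realistic noise, 8 frames."""
    spec = af.PhantomSpec(
        n_timeframes=8, snr=30.0, velocity_noise=True, seed=42
    )
    data, gt = af.generate_phantom(spec)
    return spec, data, gt


@pytest.fixture(scope="session")
def semicircle_phantom():
    """Noise-free semicircular tube (analytic tortuosity 57.08%)."""
    spec = af.PhantomSpec(
        geometry_kind="arc",
        geometry_params={"radius": 50.0, "angle": np.pi},
        lumen_radius=7.0,
        swirl_ratio=0.3,
        n_timeframes=4,
        snr=np.inf,
        seed=1,
    )
    data, gt = af.generate_phantom(spec)
    return spec, data, gt
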