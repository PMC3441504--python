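import numpy as np
import pytest

from ptwschool import ModelParams, SimConfig, TankGeometry, simulate


@pytest.fixture(scope="session")
def tank():
    return TankGeometry(radius=2.0)


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pair_track(tank, params):
    """One 120 s two-fish tank simulation at 12 fps (shared, read-only)."""
    cfg = SimConfig(tank=tank, n_fish=2, params=params, speeds=0.5,
                    duration=120.0, transient=20.0, seed=77)
    return simulate(cfg)
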