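import numpy as np
import pytest

from platonet.config import ExperimentConfig
from platonet.geometry import build_ellipsoid_shell


@pytest.fixture(scope="session")
def platelet_shell():
    """Desk-scale 4:4:1 shell shared across tests (read-only)."""
    return build_ellipsoid_shell((2.0, 2.0, 0.5), 500, seed=3)


@pytest.fixture(scope="session")
def small_shell():
    return build_ellipsoid_shell((1.0, 1.0, 0.25), 120, seed=5)


@pytest.fixture()
def tiny_config():
    """A very small, fast experiment configuration for smoke runs."""
    return ExperimentConfig(
        Lx=8.0, Ly=8.0, Lz=4.0,
        semi_axes=(1.0, 1.0, 0.25),
        n_membrane=120,
        shear_rate_reduced=1.0,
        warmup_steps=100,
        shear_warmup_steps=50,
        n_snap=5,
        K_list=(0.0003, 0.0015, 0.0030),
        seed=99,
    )
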