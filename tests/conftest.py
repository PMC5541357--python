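"""Shared fixtures: synthetic curves of known geometry."""

from __future__ import annotations

import numpy as np
import pytest

from saskit.formfactors import Body
from saskit.synthetic import NoiseModel, simulate_curve

SPHERE_R = 30.0
SPHERE_RG = np.sqrt(3.0 / 5.0) * SPHERE_R  # 23.2379...


@pytest.fixture(scope="session")
def s_grid():
    return np.linspace(0.004, 0.5, 400)


@pytest.fixture(scope="session")
def sphere_body():
    return Body("sphere", {"radius": SPHERE_R})


@pytest.fixture(scope="session")
def sphere_curve(sphere_body, s_grid):
    """Noise-free sphere curve (nominal 1e-6 relative errors)."""
    return simulate_curve(sphere_body, s_grid, NoiseModel(relative_level=0.0))


@pytest.fixture(scope="session")
def noisy_sphere_curve(sphere_body, s_grid):
    """Sphere curve with 2% intensity-proportional Gaussian noise."""
    return simulate_curve(sphere_body, s_grid, NoiseModel(relative_level=0.02, seed=42))
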