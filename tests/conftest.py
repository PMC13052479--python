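"""Shared fixtures: small seeded synthetic acquisitions and configs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from holocyte.config import OpticsConfig, PipelineConfig
from holocyte.simulate import CellSpec, SceneSpec, synthesize_frames

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def optics() -> OpticsConfig:
    return OpticsConfig()


@pytest.fixture(scope="session")
def pipe_cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def clean_scene():
    """Cell-free, noise-free, background-free scene (pure fringes)."""
    return SceneSpec(n_frames=2, cells=(), wall_positions_x=(),
                     background_poly_coeffs=(0, 0, 0, 0),
                     background_y_tilt_rad=0.0,
                     defocus_curve_coeffs=(0, 0, 0), noise_sigma=0.0)


@pytest.fixture(scope="session")
def clean_frames(clean_scene, optics):
    return synthesize_frames(clean_scene, optics)


@pytest.fixture(scope="session")
def small_cell_scene():
    """One in-focus cell, no walls/background/noise (round-trip oracle)."""
    cell = CellSpec(center_frame=2, x_center=2000)
    return SceneSpec(n_frames=5, cells=(cell,), wall_positions_x=(),
                     background_poly_coeffs=(0, 0, 0, 0),
                     background_y_tilt_rad=0.0,
                     defocus_curve_coeffs=(0, 0, 0), noise_sigma=0.0)


@pytest.fixture(scope="session")
def small_cell_frames(small_cell_scene, optics):
    return synthesize_frames(small_cell_scene, optics)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def smooth_wrapped_field(shape, seed, amplitude=12.0):
    """Residue-free wrapped field: a smooth surface with many 2*pi wraps.

    Per-pixel gradients stay below pi (worst case ~0.21*amplitude along
    the short axis with |coeffs| <= 1), so the true surface is
    recoverable up to one global 2*pi multiple.
    """
    rng = np.random.default_rng(seed)
    rows, cols = shape
    y = np.linspace(-1, 1, rows)[:, None]
    x = np.linspace(-1, 1, cols)[None, :]
    a = rng.uniform(-1, 1, size=6)
    phi = amplitude * (a[0] * x + a[1] * y + a[2] * x * y
                       + a[3] * x ** 2 + a[4] * y ** 2
                       + a[5] * np.sin(2.0 * x + 1.0 * y))
    psi = np.pi - np.mod(np.pi - phi, 2 * np.pi)
    return phi, psi
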