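"""Shared fixtures: a seeded default-regime synthetic movie and its tracked
reconstruction, reused across end-to-end tests to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pytest

from spindlekit import GaussianPSFModel
from spindlekit.pipeline import reconstruct_and_track
from spindlekit.simulate import SimulationParams, generate_movie

E2E_SEED = 1
E2E_GAMMA_STEP = 5.0  # deg/frame scripted in-plane rotation


def nominal_psf_model() -> GaussianPSFModel:
    """Widefield Gaussian PSF for a 1.42 NA objective at the default pixel size."""
    return GaussianPSFModel(
        amplitude=1.0,
        xy_center=(0.0, 0.0),
        z_center=0.0,
        sigma_x=1.3,
        sigma_y=1.3,
        sigma_z=0.30,
    )


@pytest.fixture(scope="session")
def default_movie():
    """Default acquisition regime with a gamma-rotating, drifting spindle."""
    params = SimulationParams(
        euler_increments_deg=(0.0, 0.0, E2E_GAMMA_STEP),
        centroid_velocity_um=(0.05, 0.03, 0.0),
        seed=E2E_SEED,
    )
    movie, truth = generate_movie(params)
    return params, movie, truth


@pytest.fixture(scope="session")
def tracked_default(default_movie):
    params, movie, truth = default_movie
    track = reconstruct_and_track(
        movie, truth.spindle_masks, truth.cortex_masks, nominal_psf_model()
    )
    return params, movie, truth, track


def render_ellipse(
    shape=(120, 120),
    center=(60.0, 60.0),
    semi_axes=(25.0, 10.0),
    angle_deg=0.0,
    fg=200.0,
    bg=10.0,
):
    """Render a filled 2D ellipse test image (row, col center convention)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    th = np.radians(angle_deg)
    dx = cc - center[1]
    dy = rr - center[0]
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    inside = (u / semi_axes[0]) ** 2 + (v / semi_axes[1]) ** 2 <= 1.0
    img = np.full(shape, bg, dtype=float)
    img[inside] = fg
    return img, inside
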