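"""Shared fixtures: phantoms and their clean CT/grayscale renderings.

Everything is generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from cocoscan import phantom, recon
from cocoscan.pipeline import default_seeds_for


@pytest.fixture(scope="session")
def fruit_phantom():
    """Reference mature fruit phantom at 96^3 (1.3333 mm voxels)."""
    spec = phantom.fruit_spec(grid_shape=(96, 96, 96), voxel_size_mm=1.3333)
    mu, labels, gt = phantom.make_fruit_phantom(spec)
    return spec, mu, labels, gt


@pytest.fixture(scope="session")
def fruit_gray(fruit_phantom):
    """Clean 8-bit rendering of the fruit phantom (no reconstruction)."""
    spec, mu, labels, gt = fruit_phantom
    ct = recon.Volume(
        values=200.0 * mu / spec.mu_water,
        voxel_size_mm=spec.voxel_size_mm,
        units="ct",
    )
    return recon.to_grayscale8(ct)


@pytest.fixture(scope="session")
def fruit_seeds(fruit_phantom):
    _, _, labels, _ = fruit_phantom
    return default_seeds_for(labels)


@pytest.fixture(scope="session")
def seed_phantom():
    """Dehusked seed phantom (no epicarp/mesocarp) at 96^3."""
    spec = phantom.seed_spec(grid_shape=(96, 96, 96), voxel_size_mm=0.8)
    mu, labels, gt = phantom.make_fruit_phantom(spec)
    return spec, mu, labels, gt


@pytest.fixture(scope="session")
def seed_gray(seed_phantom):
    spec, mu, labels, gt = seed_phantom
    ct = recon.Volume(
        values=200.0 * mu / spec.mu_water,
        voxel_size_mm=spec.voxel_size_mm,
        units="ct",
    )
    return recon.to_grayscale8(ct)


@pytest.fixture(scope="session")
def digital_ball():
    """Binary ball of radius 15 voxels, centred on a voxel (41^3 grid)."""
    n = 41  # odd: the ball centre coincides with a voxel centre
    z, y, x = np.mgrid[0:n, 0:n, 0:n].astype(float)
    c = (n - 1) / 2.0
    return (z - c) ** 2 + (y - c) ** 2 + (x - c) ** 2 <= 15.0**2
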