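"""Shared synthetic fixtures: every ground truth is generated, none stored."""

from __future__ import annotations

import numpy as np
import pytest

from phenogrow.synthetic_rosette import LeafSpec, RosetteSpec, render_rosette


@pytest.fixture(scope="session")
def six_leaf_rosette():
    """A mature six-leaf rosette (alternating teardrop/ellipse), off-center
    so center recovery is non-trivial."""
    leaves = tuple(
        LeafSpec(angle=a, length=90.0, width=30.0, shape=s)
        for a, s in zip((10, 70, 130, 200, 265, 320), ("teardrop", "ellipse") * 3)
    )
    spec = RosetteSpec(center=(250.0, 260.0), leaves=leaves, seed=42)
    image, truth = render_rosette(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def disk_image():
    """Noiseless bright disk of radius 50 on a dark background."""
    yy, xx = np.mgrid[:256, :256]
    radius = 50
    img = np.where((yy - 128) ** 2 + (xx - 128) ** 2 <= radius**2, 3000.0, 200.0)
    return img, radius


@pytest.fixture(scope="session")
def star_mask():
    """Five-petal star as a boolean mask, petal tips at known angles."""
    angles = (0.0, 72.0, 144.0, 216.0, 288.0)
    h = w = 301
    cy = cx = 150.0
    yy, xx = np.mgrid[:h, :w]
    phi = np.degrees(np.arctan2(yy - cy, xx - cx)) % 360.0
    rad = np.hypot(yy - cy, xx - cx)
    # petal envelope: radius bulges to 120 at each petal angle, 12 between
    # (the valley floor sits below the relative tip threshold)
    env = np.full((h, w), 12.0)
    for a in angles:
        d = np.abs((phi - a + 180.0) % 360.0 - 180.0)
        env = np.maximum(env, 120.0 * np.clip(1.0 - (d / 30.0) ** 2, 0.0, None))
    return rad <= env, angles, (cy, cx)
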