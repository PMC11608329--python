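"""Shared fixtures: analytic shapes, Gaussian-spot images, reference scenes."""

import dataclasses

import numpy as np
import pytest

from mitonuc import (BinaryMask, CalibratedImage, SceneParams, generate_scene)
from mitonuc.cli import analyze_images

PX = 0.04  # default lateral pixel size used by analytic fixtures, um


def make_bar_mask(length_um, width_um=0.5, pixel_size_um=0.1, pad_px=10):
    """Axis-aligned rectangular bar mask of the given physical size."""
    w = int(round(length_um / pixel_size_um))
    h = int(round(width_um / pixel_size_um))
    m = np.zeros((h + 2 * pad_px, w + 2 * pad_px), dtype=bool)
    m[pad_px : pad_px + h, pad_px : pad_px + w] = True
    return BinaryMask(m, pixel_size_um)


def make_capsule_mask(length_um, theta=0.0, radius_um=0.15, pixel_size_um=PX):
    """Capsule (stadium) mask: segment midline dilated to a tube."""
    n = int((length_um + 1.2) / pixel_size_um)
    yy, xx = np.mgrid[0:n, 0:n] * pixel_size_um
    c = n * pixel_size_um / 2
    u = np.array([np.cos(theta), np.sin(theta)])
    h = (length_um - 2 * radius_um) / 2
    p0 = np.array([c, c]) - h * u
    d = 2 * h * u
    den = max(float(d @ d), 1e-12)
    t = np.clip(((xx - p0[0]) * d[0] + (yy - p0[1]) * d[1]) / den, 0, 1)
    dist = np.hypot(xx - (p0[0] + t * d[0]), yy - (p0[1] + t * d[1]))
    return BinaryMask(dist <= radius_um, pixel_size_um)


def gaussian_spots(shape, centers_um, pixel_size_um=PX, amplitude=1000.0,
                   sigma_um=0.09, offset=0.0):
    """Noise-free image of Gaussian spots at physical (x, y) centers."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]] * pixel_size_um
    img = np.full(shape, float(offset))
    for (x0, y0) in centers_um:
        img += amplitude * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2)
                                  / (2 * sigma_um**2))
    return CalibratedImage(img, pixel_size_um, channel="nucleoid")


@pytest.fixture(scope="session")
def noiseless_params():
    return SceneParams(n_organelles=20, poisson_scale=0.0, gaussian_sd=0.0,
                       diffuse_fraction=0.0, seed=42)


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_params):
    return generate_scene(noiseless_params)


@pytest.fixture(scope="session")
def analyzed_noiseless(noiseless_scene):
    return analyze_images(noiseless_scene.channels["mito"],
                          noiseless_scene.channels["nucleoid"],
                          require_clusters=False)


@pytest.fixture(scope="session")
def noisy_scene():
    params = dataclasses.replace(
        SceneParams(n_organelles=30, seed=5, diffuse_fraction=0.2))
    return generate_scene(params)
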