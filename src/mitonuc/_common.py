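"""Shared infrastructure: logging, exceptions, small geometry helpers."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("mitonuc")
if not logger.handlers:  # library default: stderr handler installed by the CLI only
    logger.addHandler(logging.NullHandler())


class MitonucError(Exception):
    """Base class for all package errors."""


class CalibrationError(MitonucError):
    """Pixel size or axial spacing could not be resolved or is inconsistent."""


class InputError(MitonucError):
    """Invalid or inconsistent user input (shapes, parameters, missing files)."""


def disk_footprint(radius_px: int) -> np.ndarray:
    """Boolean disk structuring element of the given pixel radius."""
    r = int(radius_px)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def mad_scale(values: np.ndarray) -> float:
    """Robust noise scale: median absolute deviation scaled to Gaussian SD."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        return 0.0
    med = np.median(v)
    return 1.4826 * float(np.median(np.abs(v - med)))


def check_same_grid(shape_a, px_a: float, shape_b, px_b: float, what: str) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise InputError(f"{what}: shape mismatch {tuple(shape_a)} vs {tuple(shape_b)}")
    if abs(px_a - px_b) > 1e-9:
        raise InputError(f"{what}: pixel size mismatch {px_a} vs {px_b} um")
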