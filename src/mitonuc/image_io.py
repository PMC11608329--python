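"""Calibrated TIFF input/output and z-stack maximum-intensity projection.

Images carry a physical lateral pixel size (isotropic, in micrometers) and,
for z-stacks, an axial plane spacing. All downstream measurements are in
physical units, so the calibration is attached to the pixel grid at read
time and validated once.

Pixel size resolution priority: an explicit caller override wins over any
file metadata; metadata embedded in the image description (written by this
package) wins over TIFF resolution tags; if none of the three is available
the read fails rather than silently assuming a pixel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile

from ._common import CalibrationError, InputError, logger

_UNIT_UM = {2: 25400.0, 3: 10000.0}  # TIFF ResolutionUnit: inch, centimeter


@dataclass
class CalibratedImage:
    """An intensity grid with physical calibration.

    pixels        2D (y, x) or 3D (z, y, x) non-negative float array
    pixel_size_um lateral pixel edge in micrometers (isotropic x = y)
    z_step_um     axial plane spacing in micrometers (3D only)
    channel       free-text channel label, e.g. "nucleoid", "mito", "mic60"
    meta          auxiliary metadata (projection thickness, source path, ...)
    """

    pixels: np.ndarray
    pixel_size_um: float
    z_step_um: Optional[float] = None
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim not in (2, 3):
            raise InputError(f"image must be 2D or 3D, got ndim={self.pixels.ndim}")
        if not (self.pixel_size_um > 0):
            raise CalibrationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.pixels.ndim == 3 and self.z_step_um is not None and not (self.z_step_um > 0):
            raise CalibrationError(f"z_step_um must be > 0, got {self.z_step_um}")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("image contains non-finite pixel values")
        if np.any(self.pixels < 0):
            raise InputError("image contains negative intensities")

    @property
    def is_stack(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class BinaryMask:
    """A boolean grid sharing shape and calibration with its source image.

    provenance is one of {"external_file", "threshold", "detection"}.
    """

    pixels: np.ndarray
    pixel_size_um: float
    provenance: str = "threshold"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if not (self.pixel_size_um > 0):
            raise CalibrationError("mask pixel_size_um must be > 0")

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size_um**2


def _pixel_size_from_tags(tf: tifffile.TiffFile) -> Optional[float]:
    page = tf.pages[0]
    xres = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if xres is None or unit is None:
        return None
    num, den = xres.value
    if num == 0:
        return None
    unit_um = _UNIT_UM.get(int(unit.value))
    if unit_um is None:  # unit "none": resolution is not absolute
        return None
    pixels_per_unit = num / den
    return unit_um / pixels_per_unit


def _description_meta(tf: tifffile.TiffFile) -> dict:
    desc = tf.pages[0].tags.get("ImageDescription")
    if desc is None:
        return {}
    try:
        parsed = json.loads(desc.value)
    except (json.JSONDecodeError, TypeError):
        return {}
    return parsed if isinstance(parsed, dict) else {}


def read_image(
    path,
    pixel_size_um: Optional[float] = None,
    channel: str = "",
    z_step_um: Optional[float] = None,
) -> CalibratedImage:
    """Read a single- or multi-page TIFF as a calibrated image.

    Multi-page files become 3D stacks (z, y, x). The pixel size is resolved
    in priority order: explicit override > embedded description metadata >
    TIFF resolution tags; with no source available a CalibrationError is
    raised. A mismatch between an override and file metadata is logged as a
    warning, the override wins.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"cannot read image: {path} is not a file")
    try:
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            tag_px = _pixel_size_from_tags(tf)
            desc = _description_meta(tf)
    except (tifffile.TiffFileError, ValueError) as exc:
        raise InputError(f"unreadable TIFF {path}: {exc}") from exc

    if not np.issubdtype(data.dtype, np.number):
        raise InputError(f"{path}: non-numeric pixel data ({data.dtype})")
    data = np.squeeze(np.asarray(data, dtype=np.float64))
    if data.ndim not in (2, 3):
        raise InputError(f"{path}: expected 2D or 3D data, got shape {data.shape}")

    meta_px = desc.get("pixel_size_um")
    resolved = pixel_size_um if pixel_size_um is not None else (meta_px or tag_px)
    if resolved is None:
        raise CalibrationError(f"{path}: pixel size unresolvable (no override, no metadata)")
    for source, value in (("description metadata", meta_px), ("resolution tags", tag_px)):
        if pixel_size_um is not None and value and abs(value - pixel_size_um) > 1e-6:
            logger.warning(
                "%s: pixel size override %.6g um differs from %s %.6g um; using override",
                path, pixel_size_um, source, value,
            )

    zstep = z_step_um if z_step_um is not None else desc.get("z_step_um")
    return CalibratedImage(
        pixels=data,
        pixel_size_um=float(resolved),
        z_step_um=(float(zstep) if (zstep is not None and data.ndim == 3) else None),
        channel=channel or desc.get("channel", ""),
        meta={"source_path": str(path)},
    )


def write_image(path, image: CalibratedImage) -> None:
    """Write a calibrated image to TIFF, preserving values bit-exactly.

    Calibration is stored both in standard resolution tags (pixels per
    centimeter) and in a JSON image description, which round-trips the
    pixel size, axial spacing and channel label.
    """
    desc = {"pixel_size_um": image.pixel_size_um, "channel": image.channel}
    if image.z_step_um is not None:
        desc["z_step_um"] = image.z_step_um
    ppcm = 10000.0 / image.pixel_size_um
    tifffile.imwrite(
        Path(path),
        image.pixels,
        resolution=(ppcm, ppcm),
        resolutionunit="CENTIMETER",
        description=json.dumps(desc),
        metadata=None,
    )


def max_project(stack: CalibratedImage, z_range: Optional[tuple] = None) -> CalibratedImage:
    """Per-pixel maximum over selected z-planes of a 3D stack.

    z_range is an inclusive (first, last) plane index pair; the full stack
    is used when omitted. The projected physical thickness,
    (n_planes - 1) * z_step_um, is reported in the output metadata.
    """
    if not stack.is_stack:
        raise InputError("max_project requires a 3D stack")
    n = stack.pixels.shape[0]
    if z_range is None:
        lo, hi = 0, n - 1
    else:
        lo, hi = int(z_range[0]), int(z_range[1])
    if lo < 0 or hi >= n or hi < lo:
        raise InputError(f"z_range ({lo}, {hi}) invalid for {n} planes")
    planes = stack.pixels[lo : hi + 1]
    meta = dict(stack.meta)
    meta["projection_planes"] = (lo, hi)
    if stack.z_step_um is not None:
        meta["projected_thickness_um"] = (planes.shape[0] - 1) * stack.z_step_um
    return CalibratedImage(
        pixels=planes.max(axis=0),
        pixel_size_um=stack.pixel_size_um,
        z_step_um=None,
        channel=stack.channel,
        meta=meta,
    )


def read_mask(path, reference: CalibratedImage) -> BinaryMask:
    """Read an externally produced binary mask (nonzero = foreground).

    3D masks are flattened by maximum projection before comparison. The
    mask must match the reference grid; an all-zero mask is accepted with
    a warning.
    """
    img = read_image(path, pixel_size_um=reference.pixel_size_um, channel="mask")
    pixels = img.pixels
    if pixels.ndim == 3:
        pixels = pixels.max(axis=0)
    ref_shape = reference.pixels.shape[-2:]
    if pixels.shape != tuple(ref_shape):
        raise InputError(
            f"mask shape {pixels.shape} does not match reference {tuple(ref_shape)}"
        )
    mask = pixels > 0
    if not mask.any():
        logger.warning("%s: mask is entirely empty", path)
    return BinaryMask(pixels=mask, pixel_size_um=reference.pixel_size_um,
                      provenance="external_file")


def write_mask(path, mask: BinaryMask) -> None:
    """Write a mask as an 8-bit 0/255 TIFF with calibration tags."""
    img = CalibratedImage(
        pixels=mask.pixels.astype(np.float64) * 255.0,
        pixel_size_um=mask.pixel_size_um,
        channel="mask",
    )
    out = img.pixels.astype(np.uint8)
    desc = {"pixel_size_um": mask.pixel_size_um, "channel": "mask"}
    ppcm = 10000.0 / mask.pixel_size_um
    tifffile.imwrite(Path(path), out, resolution=(ppcm, ppcm),
                     resolutionunit="CENTIMETER", description=json.dumps(desc),
                     metadata=None)


def save_table(df: pd.DataFrame, path) -> None:
    """Write a result table as CSV with a single header line."""
    df.to_csv(Path(path), index=False)


def save_json(obj: dict, path) -> None:
    """Write a run summary / report as pretty-printed JSON."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
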