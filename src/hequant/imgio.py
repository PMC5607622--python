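"""Image I/O, channel handling, field-of-view estimation and spatial calibration.

Conventions used throughout the package:

* rasters are row-major numpy arrays, 0-based, origin at the top-left;
* a *fundus image* is an ``H x W x 3`` uint8 array wrapped in
  :class:`FundusImage`;
* an *intensity image* is a plain ``H x W`` float64 array with values in
  ``[0, 1]``;
* a *binary mask* is a plain ``H x W`` bool array.

Fundus photographs show a circular imaged field (the field of view, FOV)
on a near-black camera surround; :func:`estimate_fov_mask` recovers that
circle so downstream detection can ignore the surround.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger("hequant")

__all__ = [
    "Calibration",
    "FundusImage",
    "read_image",
    "write_mask",
    "rgb_to_gray",
    "extract_green",
    "estimate_fov_mask",
    "derive_calibration",
    "default_calibration",
]

#: BT.601 luma weights for RGB -> gray conversion.
GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)

#: Linear retinal extent of one degree of visual field in the emmetropic
#: eye, in millimetres.  Used to turn a field-of-view angle plus a pixel
#: diameter into a mm-per-pixel scale.
MM_PER_DEGREE = 0.288

#: Field-of-view angle (degrees) assumed when no calibration is supplied.
DEFAULT_FOV_DEGREES = 50.0


@dataclass(frozen=True)
class Calibration:
    """Isotropic spatial calibration of a fundus photograph.

    Parameters
    ----------
    mm_per_pixel : float
        Physical size of one pixel on the retina, millimetres.
    source : str
        Provenance tag: ``user_supplied``, ``fov_derived`` or ``default``.
    """

    mm_per_pixel: float
    source: str = "user_supplied"

    _SOURCES = ("user_supplied", "fov_derived", "default")

    def __post_init__(self) -> None:
        if not (self.mm_per_pixel > 0):
            raise ValueError(f"mm_per_pixel must be > 0, got {self.mm_per_pixel}")
        if self.source not in self._SOURCES:
            raise ValueError(f"unknown calibration source {self.source!r}")


@dataclass
class FundusImage:
    """An 8-bit RGB colour fundus photograph.

    Attributes
    ----------
    pixels : numpy.ndarray
        ``H x W x 3`` uint8 raster.
    fov_mask : numpy.ndarray, optional
        ``H x W`` bool mask, True inside the circular imaged field.
    calibration : Calibration, optional
    """

    pixels: np.ndarray
    fov_mask: Optional[np.ndarray] = None
    calibration: Optional[Calibration] = field(default=None)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError(f"image too small ({px.shape[0]}x{px.shape[1]}), need >= 32x32")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("pixel values outside [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px
        if self.fov_mask is not None:
            m = np.asarray(self.fov_mask, dtype=bool)
            if m.shape != px.shape[:2]:
                raise ValueError("fov_mask shape does not match image")
            self.fov_mask = m

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the raster."""
        return self.pixels.shape[:2]


def read_image(path) -> FundusImage:
    """Read a PNG/TIFF/JPEG raster into a :class:`FundusImage`.

    Grayscale inputs are replicated to three channels with a warning;
    16-bit inputs are down-scaled to 8 bits by integer division (65535
    maps to 255) with a warning; an alpha channel is dropped.

    Raises
    ------
    IOError
        If the file is missing or cannot be decoded.
    ValueError
        If the decoded raster is smaller than 32 x 32.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise IOError(f"cannot read image: {path} (file not found)")
    except Exception as exc:  # decoder errors vary by backend
        raise IOError(f"cannot read image: {path} ({exc})")

    arr = np.asarray(arr)
    if arr.ndim == 2:
        logger.warning("%s is single-channel; replicating to RGB", path)
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"cannot read image: {path} (unsupported shape {arr.shape})")

    if arr.dtype == np.uint16:
        logger.warning("%s is 16-bit; down-scaling to 8-bit (integer division by 257)", path)
        arr = (arr // 257).astype(np.uint8)
    elif arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)

    return FundusImage(pixels=arr)


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG (False -> 0, True -> 255)."""
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def rgb_to_gray(img: FundusImage) -> np.ndarray:
    """BT.601 grayscale conversion to a [0, 1] intensity image.

    ``v = (0.2989 R + 0.5870 G + 0.1140 B) / 255``.
    """
    r, g, b = GRAY_WEIGHTS
    px = img.pixels.astype(np.float64)
    v = (r * px[:, :, 0] + g * px[:, :, 1] + b * px[:, :, 2]) / 255.0
    return np.clip(v, 0.0, 1.0)


def extract_green(img: FundusImage) -> np.ndarray:
    """Green plane as a [0, 1] intensity image (``v = G / 255``)."""
    return img.pixels[:, :, 1].astype(np.float64) / 255.0


def estimate_fov_mask(img: FundusImage, dark_threshold: int = 10) -> np.ndarray:
    """Estimate the circular field-of-view mask of a fundus photograph.

    A pixel is "lit" when its maximum channel value exceeds
    ``dark_threshold``.  The lit region is morphologically closed with a
    radius-5 disk and its largest connected component is returned.

    Returns the whole-frame mask with a warning when the lit region
    covers more than 99 % of the frame (no surround present).

    Raises
    ------
    ValueError
        If the image is entirely dark.
    """
    lit = img.pixels.max(axis=2) > dark_threshold
    if not lit.any():
        raise ValueError("cannot estimate FOV: image is entirely dark")
    yy, xx = np.ogrid[-5:6, -5:6]
    # edge-pad so closing does not erode a region touching the frame border
    padded = np.pad(lit, 6, mode="edge")
    lit = ndi.binary_closing(padded, structure=(yy * yy + xx * xx) <= 25)[6:-6, 6:-6]
    labels, n = ndi.label(lit)
    if n == 0:
        raise ValueError("cannot estimate FOV: image is entirely dark")
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    if mask.sum() > 0.99 * mask.size:
        logger.warning("lit region covers >99%% of the frame; using whole-frame FOV")
        return np.ones_like(mask)
    return mask


def derive_calibration(fov_diameter_px: float, fov_degrees: float) -> Calibration:
    """Millimetre-per-pixel scale from a field-of-view angle and diameter.

    ``mm_per_pixel = fov_degrees * 0.288 / fov_diameter_px`` with
    0.288 mm/degree the emmetropic-eye retinal scale.
    """
    if not (fov_diameter_px > 0):
        raise ValueError(f"fov_diameter_px must be > 0, got {fov_diameter_px}")
    if not (fov_degrees > 0):
        raise ValueError(f"fov_degrees must be > 0, got {fov_degrees}")
    return Calibration(
        mm_per_pixel=fov_degrees * MM_PER_DEGREE / fov_diameter_px,
        source="fov_derived",
    )


def default_calibration(img: FundusImage, fov_degrees: float = DEFAULT_FOV_DEGREES) -> Calibration:
    """Fallback calibration assuming a 50-degree acquisition protocol.

    The FOV diameter is estimated from the image (equivalent-area
    circle of the estimated FOV mask).  The result is tagged
    ``default`` and logged; supply ``mm_per_pixel`` explicitly for
    quantitative work.
    """
    fov = img.fov_mask if img.fov_mask is not None else estimate_fov_mask(img)
    diameter = 2.0 * np.sqrt(fov.sum() / np.pi)
    cal = derive_calibration(diameter, fov_degrees)
    logger.warning(
        "no calibration supplied; assuming %.0f-degree FOV of diameter %.0f px "
        "-> %.6f mm/pixel", fov_degrees, diameter, cal.mm_per_pixel,
    )
    return Calibration(mm_per_pixel=cal.mm_per_pixel, source="default")
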