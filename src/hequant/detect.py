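"""Two-pronged hard-exudate detection.

Hard exudates (HEs) span a wide brightness range, so detection runs twice
with different scales and thresholds and the results are unioned:

* **step 1 — bright HEs**: grayscale image -> white top-hat with a disk of
  radius one-fourth of the image width (background flattening) ->
  contrast-limited adaptive histogram equalization -> fixed threshold 0.37;
* **step 2 — faint HEs**: green plane (where faint HEs are best
  contrasted) -> white top-hat with a disk of radius one-twenty-fifth of
  the image width -> CLAHE -> threshold 0.25.

Both masks are intersected with the field-of-view mask (equalization
responds to the FOV rim; the surround is camera matting, not retina).
Everything is deterministic: identical inputs give bit-identical masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import exposure

from .imgio import FundusImage, estimate_fov_mask, extract_green, rgb_to_gray
from .morphology import StructuringElement, white_top_hat

__all__ = [
    "DetectParams",
    "adaptive_hist_eq",
    "binarize",
    "detect_step1",
    "detect_step2",
    "combine",
    "detect_exudates",
]


@dataclass(frozen=True)
class DetectParams:
    """Tunable parameters of the two-step detector.

    Defaults are the published operating point: thresholds 0.37 (bright)
    and 0.25 (faint) on the equalized [0, 1] scale, disk radii 1/4 and
    1/25 of the image width.  The equalization geometry (8 x 8 tiles,
    clip limit 0.01) follows the defaults of mainstream CLAHE
    implementations and is configurable because the published thresholds
    may be coupled to it.
    """

    step1_radius_frac: float = 0.25
    step1_threshold: float = 0.37
    step2_radius_frac: float = 1.0 / 25.0
    step2_threshold: float = 0.25
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip: float = 0.01

    def __post_init__(self) -> None:
        for name in ("step1_threshold", "step2_threshold"):
            t = getattr(self, name)
            if not (0.0 < t < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {t}")
        for name in ("step1_radius_frac", "step2_radius_frac"):
            f = getattr(self, name)
            if not (0.0 < f <= 0.5):
                raise ValueError(f"{name} must be in (0, 0.5], got {f}")
        ty, tx = self.clahe_tiles
        if ty < 1 or tx < 1:
            raise ValueError(f"clahe_tiles must be >= 1, got {self.clahe_tiles}")
        if not (0.0 < self.clahe_clip <= 1.0):
            raise ValueError(f"clahe_clip must be in (0, 1], got {self.clahe_clip}")

    def radius_px(self, width: int, step: int) -> int:
        frac = self.step1_radius_frac if step == 1 else self.step2_radius_frac
        return max(1, round(frac * width))


def adaptive_hist_eq(
    img: np.ndarray, tiles: tuple[int, int] = (8, 8), clip: float = 0.01
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization (CLAHE).

    The image is split into ``tiles`` (rows, cols) regions; each region is
    histogram-equalized with its histogram clipped at ``clip`` (fraction
    of region pixels per bin) and the per-region mappings are bilinearly
    interpolated.  With a single tile and ``clip=1`` this reduces to
    global histogram equalization.  Output values lie in [0, 1].
    """
    img = np.asarray(img, dtype=np.float64)
    ty, tx = int(tiles[0]), int(tiles[1])
    if ty < 1 or tx < 1 or ty > img.shape[0] or tx > img.shape[1]:
        raise ValueError(f"invalid tile grid {tiles} for image {img.shape}")
    if not (0.0 < clip <= 1.0):
        raise ValueError(f"clip must be in (0, 1], got {clip}")
    kernel = (max(1, img.shape[0] // ty), max(1, img.shape[1] // tx))
    out = exposure.equalize_adapthist(np.clip(img, 0.0, 1.0), kernel_size=kernel, clip_limit=clip)
    return np.clip(out, 0.0, 1.0)


def binarize(img: np.ndarray, threshold: float) -> np.ndarray:
    """Threshold an intensity image: True iff value is *strictly* above."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return np.asarray(img, dtype=np.float64) > threshold


def _detect_one_step(
    intensity: np.ndarray,
    fov: np.ndarray,
    radius: int,
    threshold: float,
    p: DetectParams,
    stages: Optional[dict] = None,
) -> np.ndarray:
    th = white_top_hat(intensity, StructuringElement(radius))
    if np.ptp(th) == 0.0:
        # constant residue (e.g. an all-black or perfectly flat frame):
        # there is no structure to enhance, and equalizing a degenerate
        # histogram would saturate the whole frame
        mask = np.zeros_like(th, dtype=bool)
        if stages is not None:
            stages.update(top_hat=th, equalized=th.copy())
        return mask
    eq = adaptive_hist_eq(th, p.clahe_tiles, p.clahe_clip)
    mask = binarize(eq, threshold) & fov
    if stages is not None:
        stages.update(top_hat=th, equalized=eq)
    return mask


def _fov_of(img: FundusImage) -> np.ndarray:
    return img.fov_mask if img.fov_mask is not None else estimate_fov_mask(img)


def detect_step1(
    img: FundusImage, p: DetectParams = DetectParams(), stages: Optional[dict] = None
) -> np.ndarray:
    """Bright-HE detection on the grayscale image (disk radius W/4, threshold 0.37)."""
    return _detect_one_step(
        rgb_to_gray(img), _fov_of(img), p.radius_px(img.shape[1], 1), p.step1_threshold, p, stages
    )


def detect_step2(
    img: FundusImage, p: DetectParams = DetectParams(), stages: Optional[dict] = None
) -> np.ndarray:
    """Faint-HE detection on the green plane (disk radius W/25, threshold 0.25)."""
    return _detect_one_step(
        extract_green(img), _fov_of(img), p.radius_px(img.shape[1], 2), p.step2_threshold, p, stages
    )


def combine(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Pixelwise OR of two equally sized binary masks."""
    m1 = np.asarray(m1, dtype=bool)
    m2 = np.asarray(m2, dtype=bool)
    if m1.shape != m2.shape:
        raise ValueError(f"mask dimensions differ: {m1.shape} vs {m2.shape}")
    return m1 | m2


def detect_exudates(
    img: FundusImage, p: DetectParams = DetectParams(), stages: Optional[dict] = None
) -> np.ndarray:
    """Full proposed detector: union of the bright and faint prongs."""
    s1 = {} if stages is not None else None
    s2 = {} if stages is not None else None
    m1 = detect_step1(img, p, s1)
    m2 = detect_step2(img, p, s2)
    if stages is not None:
        stages["step1"] = dict(s1, mask=m1)
        stages["step2"] = dict(s2, mask=m2)
    return combine(m1, m2)
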