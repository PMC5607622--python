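"""Seeded synthetic fundus scenes with per-class ground truth.

Real colour fundus photographs of diabetic retinopathy show bright hard
exudates (HEs) against a reddish retinal background, alongside the
structures that confound brightness-based detection: the optic disc, the
vessel tree with its bright centerline reflections, and cotton-wool
spots.  The generator emulates that scene at the gray-level ranges
characterised on an exemplar photograph — HEs 85–200, cotton-wool spots
80–130, optic disc 90–200, vessel reflections 80–110 on the 8-bit
grayscale — and records a crisp per-class truth mask *before* blur and
noise, so detection metrics have an unambiguous reference.

Everything geometric (blob radii, vessel widths, cluster sizes) is an
invented, parameterised stand-in: no morphometry is reproduced, only the
intensity structure.  Scenes are deterministic functions of the spec
(including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .imgio import GRAY_WEIGHTS, FundusImage
from .quantify import ExclusionBox

__all__ = ["SceneSpec", "SceneTruth", "generate_scene", "scene_census", "confounder_boxes"]

_W = np.array(GRAY_WEIGHTS)

#: Background colour of the synthetic retina (R, G, B), 8-bit.
BACKGROUND_RGB = np.array([160.0, 80.0, 30.0])

#: Colour directions (unit-free tints) used when painting structures at a
#: target gray level.
_TINTS = {
    "disc": np.array([1.20, 1.00, 0.55]),
    "vessel": np.array([1.50, 0.75, 0.40]),
    "reflection": np.array([1.00, 1.00, 0.95]),
    "he": np.array([1.15, 1.00, 0.50]),
    "cws": np.array([1.00, 1.00, 0.88]),
}

_MAX_PLACEMENT_ATTEMPTS = 1000


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic fundus scene.

    Gray-level ranges are 8-bit grayscale bounds per structure class;
    ``faint_green_excess`` is the green-plane contrast of faint HEs over
    their local background on the [0, 1] scale (default 0.06, i.e. about
    15 gray levels); ``illumination_gradient`` is the relative amplitude
    of the smooth shading field; ``noise_sd`` the additive Gaussian
    noise, as a fraction of full scale.
    """

    height: int = 512
    width: int = 512
    seed: int = 0
    n_bright_he: int = 6
    n_faint_he: int = 6
    n_cws: int = 2
    he_gray_range: tuple[int, int] = (85, 200)
    cws_gray_range: tuple[int, int] = (80, 130)
    disc_gray_range: tuple[int, int] = (90, 200)
    vessel_reflection_range: tuple[int, int] = (80, 110)
    faint_green_excess: float = 0.06
    illumination_gradient: float = 0.3
    noise_sd: float = 0.01
    include_disc: bool = True
    include_vessels: bool = True

    def __post_init__(self) -> None:
        if self.height < 32 or self.width < 32:
            raise ValueError("scene must be at least 32 x 32")
        for name in ("he_gray_range", "cws_gray_range", "disc_gray_range",
                     "vessel_reflection_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 255):
                raise ValueError(f"{name} must satisfy 0 <= low <= high <= 255")
        for name in ("n_bright_he", "n_faint_he", "n_cws"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.faint_green_excess < 0.3):
            raise ValueError("faint_green_excess must be in (0, 0.3)")
        if not (0.0 <= self.illumination_gradient <= 0.4):
            raise ValueError("illumination_gradient must be in [0, 0.4]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SceneTruth:
    """Per-class ground truth of a generated scene (recorded pre-noise)."""

    he_bright_mask: np.ndarray
    he_faint_mask: np.ndarray
    cws_mask: np.ndarray
    disc_mask: np.ndarray
    vessel_mask: np.ndarray
    reflection_mask: np.ndarray
    fov_mask: np.ndarray
    n_bright_clusters: int
    n_faint_blobs: int
    n_cws_blobs: int
    pre_noise_rgb: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def he_mask(self) -> np.ndarray:
        """Union of bright and faint hard-exudate truth."""
        return self.he_bright_mask | self.he_faint_mask


def _rgb_for_gray(gray: float, tint: np.ndarray) -> np.ndarray:
    """RGB triple (float, 0–255) whose BT.601 gray equals ``gray``."""
    rgb = gray * tint / float(_W @ tint)
    return np.clip(rgb, 0.0, 255.0)


def _ellipse_mask(H: int, W: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:H, 0:W]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = dx * c + dy * s
    v = -dx * s + dy * c
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _dilate(mask: np.ndarray, r: int) -> np.ndarray:
    if r <= 0 or not mask.any():
        return mask
    ax = np.arange(-r, r + 1)
    return ndi.binary_dilation(mask, structure=(ax[:, None] ** 2 + ax[None, :] ** 2) <= r * r)


class _Painter:
    """Mutable scene state shared by the construction stages."""

    def __init__(self, spec: SceneSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        H, W = spec.height, spec.width
        self.H, self.W = H, W
        self.fov_radius = 0.475 * min(H, W)
        self.cy, self.cx = H / 2.0, W / 2.0
        yy, xx = np.mgrid[0:H, 0:W]
        self.fov = (yy - self.cy) ** 2 + (xx - self.cx) ** 2 <= self.fov_radius ** 2
        self.img = np.zeros((H, W, 3))
        # region no new structure may intrude on, pre-dilated by the
        # separation margin so overlap checks are single intersections
        self.forbidden = np.zeros((H, W), dtype=bool)
        self.sep = 3

    def reserve(self, mask: np.ndarray) -> None:
        self.forbidden |= _dilate(mask, self.sep)

    def placeable(self, mask: np.ndarray) -> bool:
        return mask.any() and not (mask & self.forbidden).any() and not (mask & ~self.fov).any()


def _paint_background(p: _Painter) -> None:
    spec, rng = p.spec, p.rng
    H, W = p.H, p.W
    yy, xx = np.mgrid[0:H, 0:W]
    # smooth shading, brightening toward the nasal (disc) side: the macula
    # is the darker region of a fundus photograph.  Dominated by a tilted
    # plane (which a flat structuring element removes exactly in the
    # top-hat) plus a broad, gentle bump for curvature.
    theta = rng.uniform(-np.pi / 3, np.pi / 3)  # bright direction, 0 = east
    plane = ((yy - p.cy) * np.sin(theta) + (xx - p.cx) * np.cos(theta)) / max(H, W)
    by, bx = rng.uniform(0.35, 0.65), rng.uniform(0.60, 0.80)
    bump = np.exp(-(((yy / H - by) ** 2 + (xx / W - bx) ** 2) / 0.30))
    fld = 0.75 * (plane + 0.5) + 0.25 * bump
    fld = (fld - fld.min()) / max(np.ptp(fld), 1e-12)
    shade = 1.0 - spec.illumination_gradient * (1.0 - fld)
    p.bg = BACKGROUND_RGB[None, None, :] * shade[:, :, None]
    p.img[:] = p.bg
    p.img[~p.fov] = rng.integers(0, 4, size=((~p.fov).sum(), 3))


def _paint_disc(p: _Painter) -> np.ndarray:
    spec, rng = p.spec, p.rng
    if not spec.include_disc:
        return np.zeros((p.H, p.W), dtype=bool)
    lo, hi = spec.disc_gray_range
    ry = rng.uniform(0.11, 0.14) * p.fov_radius
    rx = ry * rng.uniform(0.78, 0.9)
    cy = p.cy + rng.uniform(-0.1, 0.1) * p.fov_radius
    cx = p.cx + 0.62 * p.fov_radius  # nasal side = east
    mask = _ellipse_mask(p.H, p.W, cy, cx, ry, rx) & p.fov
    yy, xx = np.mgrid[0:p.H, 0:p.W]
    rho = np.clip(np.sqrt(((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2), 0.0, 1.0)
    gray = np.clip(lo + 2 + (hi - lo - 4) * (1.0 - rho) ** 0.6, lo + 2, hi - 2)
    tint = _TINTS["disc"] / float(_W @ _TINTS["disc"])
    p.img[mask] = np.clip(gray[mask, None] * tint[None, :], 0, 255)
    p.reserve(mask)
    return mask


def _paint_vessels(p: _Painter) -> tuple[np.ndarray, np.ndarray]:
    spec, rng = p.spec, p.rng
    vessel = np.zeros((p.H, p.W), dtype=bool)
    reflect = np.zeros((p.H, p.W), dtype=bool)
    if not spec.include_vessels:
        return vessel, reflect
    lo_r, hi_r = spec.vessel_reflection_range
    n_paths = int(rng.integers(2, 5))
    origin = np.array([p.cy, p.cx + (0.62 * p.fov_radius if spec.include_disc else 0.0)])
    drawn = []
    for _ in range(n_paths):
        width = int(rng.integers(2, 5))
        theta = rng.uniform(0.6 * np.pi, 1.4 * np.pi)  # head west, into the macula
        pos = origin.astype(float).copy()
        path: list[tuple[int, int]] = []
        for _step in range(int(1.2 * max(p.H, p.W))):
            theta += rng.normal(0.0, 0.12)
            pos += np.array([np.sin(theta), np.cos(theta)])
            iy, ix = int(round(pos[0])), int(round(pos[1]))
            if not (0 <= iy < p.H and 0 <= ix < p.W) or not p.fov[iy, ix]:
                break
            path.append((iy, ix))
        if len(path) < 10:
            continue
        half = max(1, width // 2)
        seg = np.zeros((p.H, p.W), dtype=bool)
        for iy, ix in path:
            y0, y1 = max(iy - half, 0), min(iy + half + 1, p.H)
            x0, x1 = max(ix - half, 0), min(ix + half + 1, p.W)
            seg[y0:y1, x0:x1] = True
        seg &= p.fov
        vessel |= seg
        # bright centerline reflections on a random 30% of path length
        n_steps = len(path)
        chosen = np.zeros(n_steps, dtype=bool)
        target = int(0.3 * n_steps)
        while chosen.sum() < target:
            start = int(rng.integers(0, n_steps))
            run = int(rng.integers(8, 30))
            chosen[start:start + run] = True
        refl = np.zeros((p.H, p.W), dtype=bool)
        for flag, (iy, ix) in zip(chosen, path):
            if flag:
                refl[iy, ix] = True
        drawn.append((seg, refl, rng.uniform(0.80, 0.88), rng.uniform(lo_r + 2, hi_r - 2)))
    # paint all vessel bodies first so no stroke overwrites a reflection.
    # Vessels keep a constant *fractional* contrast to the local shaded
    # background (slightly deeper in green/blue: they are dark red).
    for seg, _refl, f, _g in drawn:
        factors = np.array([min(f + 0.08, 0.97), f - 0.03, f - 0.03])
        p.img[seg] = p.bg[seg] * factors[None, :]
    for seg, refl, _gv, gray_refl in drawn:
        refl &= seg
        p.img[refl] = _rgb_for_gray(gray_refl, _TINTS["reflection"])
        reflect |= refl
    p.reserve(vessel)
    return vessel, reflect


def _sample_blob(p: _Painter, region_x_max: float, r_lo: float, r_hi: float,
                 center: Optional[np.ndarray] = None, spread: float = 0.0) -> np.ndarray:
    rng = p.rng
    if center is None:
        margin = 0.1 * p.fov_radius
        while True:
            cy = rng.uniform(p.cy - p.fov_radius + margin, p.cy + p.fov_radius - margin)
            cx = rng.uniform(p.cx - p.fov_radius + margin, min(region_x_max, p.cx + p.fov_radius))
            if (cy - p.cy) ** 2 + (cx - p.cx) ** 2 <= (p.fov_radius - margin) ** 2:
                break
    else:
        cy = center[0] + rng.uniform(-spread, spread)
        cx = center[1] + rng.uniform(-spread, spread)
    ry = rng.uniform(r_lo, r_hi)
    rx = rng.uniform(r_lo, r_hi)
    return _ellipse_mask(p.H, p.W, cy, cx, ry, rx, rng.uniform(0, np.pi))


def _paint_bright_he(p: _Painter) -> tuple[np.ndarray, int]:
    spec, rng = p.spec, p.rng
    mask = np.zeros((p.H, p.W), dtype=bool)
    lo, hi = spec.he_gray_range
    g_lo = (lo + hi) / 2.0  # bright HEs occupy the upper half of the range
    region_x_max = p.cx  # macular half, away from the nasal disc
    placed = 0
    for _ in range(spec.n_bright_he):
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            n_blobs = int(rng.integers(1, 9))
            centre = None
            cluster = np.zeros((p.H, p.W), dtype=bool)
            ok = True
            for b in range(n_blobs):
                blob = _sample_blob(p, region_x_max, 1.0, 6.0, center=centre, spread=10.0)
                if centre is None:
                    ys, xs = np.nonzero(blob)
                    if ys.size == 0:
                        ok = False
                        break
                    centre = np.array([ys.mean(), xs.mean()])
                cluster |= blob
            if not ok or not p.placeable(cluster):
                continue
            gray = rng.uniform(g_lo + 2, hi - 2)
            p.img[cluster] = _rgb_for_gray(gray, _TINTS["he"])
            mask |= cluster
            p.reserve(cluster)
            placed += 1
            break
        else:
            raise RuntimeError(
                "could not place bright hard-exudate cluster after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts (overcrowded scene spec)"
            )
    return mask, placed


def _paint_faint_he(p: _Painter) -> tuple[np.ndarray, int]:
    spec, rng = p.spec, p.rng
    mask = np.zeros((p.H, p.W), dtype=bool)
    lo, hi = spec.he_gray_range
    half_hi = (lo + hi) / 2.0
    excess = spec.faint_green_excess * 255.0
    placed = 0
    for _ in range(spec.n_faint_he):
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            blob = _sample_blob(p, p.cx, 3.0, 6.0)
            if not p.placeable(blob):
                continue
            # green channel sits `excess` above local background; grayscale
            # stays in the lower half of the HE range, just above background
            bg = p.bg[blob]
            g = np.clip(bg[:, 1] + excess, 0, 255)
            gray_t = np.clip(_W @ bg.T + 6.0, lo + 1.0, half_hi)
            b = bg[:, 2]
            r = np.clip((gray_t - _W[1] * g - _W[2] * b) / _W[0], 0, 255)
            p.img[blob] = np.stack([r, g, b], axis=1)
            mask |= blob
            p.reserve(blob)
            placed += 1
            break
        else:
            raise RuntimeError(
                "could not place faint hard exudate after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts (overcrowded scene spec)"
            )
    return mask, placed


def _paint_cws(p: _Painter) -> tuple[np.ndarray, int]:
    spec, rng = p.spec, p.rng
    mask = np.zeros((p.H, p.W), dtype=bool)
    lo, hi = spec.cws_gray_range
    placed = 0
    for _ in range(spec.n_cws):
        for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
            blob = _sample_blob(p, p.cx + 0.4 * p.fov_radius, 8.0, 16.0)
            if not p.placeable(blob):
                continue
            gray = rng.uniform(lo + 4, hi - 4)
            rgb = _rgb_for_gray(gray, _TINTS["cws"])
            # fuzzy boundary: blur the blob's alpha, keep the crisp mask as truth
            alpha = ndi.gaussian_filter(blob.astype(np.float64), sigma=2.0)
            alpha = np.clip(alpha, 0.0, 1.0)
            p.img = p.img * (1.0 - alpha[:, :, None]) + rgb[None, None, :] * alpha[:, :, None]
            p.img[~p.fov] = np.clip(p.img[~p.fov], 0, 5)
            mask |= blob
            p.reserve(blob)
            placed += 1
            break
        else:
            raise RuntimeError(
                "could not place cotton-wool spot after "
                f"{_MAX_PLACEMENT_ATTEMPTS} attempts (overcrowded scene spec)"
            )
    return mask, placed


def generate_scene(spec: SceneSpec) -> tuple[FundusImage, SceneTruth]:
    """Render a synthetic fundus scene and its ground truth.

    Construction order: circular FOV (diameter 0.95·min(H, W)) on a
    near-black surround; shaded reddish background; optic disc; vessel
    tree with centerline reflections; bright HE clusters (1–8 elliptical
    blobs each) in the macular half; faint HEs with a controlled
    green-plane excess; fuzzy cotton-wool spots; additive Gaussian noise
    inside the FOV.  Truth masks are recorded before blur and noise.
    Deterministic: the same spec yields bit-identical output.

    Raises
    ------
    RuntimeError
        If a lesion cannot be placed within 1000 rejection-sampling
        attempts (overcrowded spec), naming the class.
    """
    p = _Painter(spec)
    _paint_background(p)
    disc = _paint_disc(p)
    vessel, reflect = _paint_vessels(p)
    bright, n_bright = _paint_bright_he(p)
    faint, n_faint = _paint_faint_he(p)
    cws, n_cws = _paint_cws(p)

    pre_noise = p.img.copy()
    img = p.img
    if spec.noise_sd > 0:
        noise = p.rng.normal(0.0, spec.noise_sd * 255.0, size=img.shape)
        img = img + noise * p.fov[:, :, None]
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = SceneTruth(
        he_bright_mask=bright, he_faint_mask=faint, cws_mask=cws,
        disc_mask=disc, vessel_mask=vessel, reflection_mask=reflect,
        fov_mask=p.fov, n_bright_clusters=n_bright, n_faint_blobs=n_faint,
        n_cws_blobs=n_cws, pre_noise_rgb=pre_noise,
    )
    fundus = FundusImage(pixels=pixels, fov_mask=p.fov)
    return fundus, truth


_CENSUS_CLASSES = (
    ("he_bright", "he_bright_mask"),
    ("he_faint", "he_faint_mask"),
    ("cws", "cws_mask"),
    ("disc", "disc_mask"),
    ("vessel", "vessel_mask"),
    ("reflection", "reflection_mask"),
)


def scene_census(truth: SceneTruth) -> dict:
    """Per-class component counts and pixel areas of a scene's truth."""
    out = {}
    eight = np.ones((3, 3), dtype=bool)
    for name, attr in _CENSUS_CLASSES:
        mask = getattr(truth, attr)
        _, n = ndi.label(mask, structure=eight)
        out[name] = {"components": int(n), "pixels": int(mask.sum())}
    out["he_bright"]["placed"] = truth.n_bright_clusters
    out["he_faint"]["placed"] = truth.n_faint_blobs
    out["cws"]["placed"] = truth.n_cws_blobs
    return out


def confounder_boxes(truth: SceneTruth, margin: int = 10, tile: int = 48) -> list[ExclusionBox]:
    """Exclusion boxes covering every confounder region of a scene.

    Emulates the manual outlier-removal step on a synthetic scene: one
    box per connected component of the optic disc and cotton-wool masks,
    and — because a single bounding box of the vessel tree would blank
    most of the field — a string of small boxes (``tile`` pixels) along
    the vessel/reflection course, each grown by ``margin`` pixels to
    absorb the filter halo around dark vessels.
    """
    boxes = []
    eight = np.ones((3, 3), dtype=bool)
    H, W = truth.fov_mask.shape
    for attr in ("disc_mask", "cws_mask"):
        mask = getattr(truth, attr)
        labels, n = ndi.label(mask, structure=eight)
        for sl in ndi.find_objects(labels):
            if sl is None:
                continue
            ys, xs = sl
            boxes.append(ExclusionBox(
                x0=max(xs.start - margin, 0), y0=max(ys.start - margin, 0),
                x1=min(xs.stop + margin, W), y1=min(ys.stop + margin, H),
            ))
    course = truth.vessel_mask | truth.reflection_mask
    for ty in range(0, H, tile):
        for tx in range(0, W, tile):
            cell = course[ty:ty + tile, tx:tx + tile]
            if not cell.any():
                continue
            ys, xs = np.nonzero(cell)
            boxes.append(ExclusionBox(
                x0=max(tx + xs.min() - margin, 0), y0=max(ty + ys.min() - margin, 0),
                x1=min(tx + xs.max() + 1 + margin, W), y1=min(ty + ys.max() + 1 + margin, H),
            ))
    return boxes
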