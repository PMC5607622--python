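import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hequant import SceneSpec, baseline_detect, generate_scene
from hequant.detect import DetectParams, detect_step1, detect_step2

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_scene():
    """One canonical 512x512 scene with all structure classes present."""
    return generate_scene(SceneSpec(seed=1))


@pytest.fixture(scope="session")
def default_masks(default_scene):
    """Detection masks of every method on the canonical scene."""
    img, _ = default_scene
    p = DetectParams()
    m1 = detect_step1(img, p)
    m2 = detect_step2(img, p)
    return {"step1": m1, "step2": m2, "proposed": m1 | m2, "baseline": baseline_detect(img)}


@pytest.fixture(scope="session")
def blank_scene():
    """Lesion-free, confounder-free retina (background + shading + noise)."""
    return generate_scene(
        SceneSpec(seed=2, n_bright_he=0, n_faint_he=0, n_cws=0,
                  include_disc=False, include_vessels=False)
    )


def bruteforce_white_tophat(img: np.ndarray, radius: int) -> np.ndarray:
    """Independent sliding-window oracle for the white top-hat.

    Exhaustive per-pixel min/max over the Euclidean disk, window clipped
    to the raster; kept free of any shared code with the implementation.
    """
    H, W = img.shape

    def _scan(src, reduce_fn):
        out = np.empty_like(src)
        for y in range(H):
            for x in range(W):
                vals = []
                for dj in range(-radius, radius + 1):
                    for di in range(-radius, radius + 1):
                        if dj * dj + di * di <= radius * radius:
                            yy, xx = y + dj, x + di
                            if 0 <= yy < H and 0 <= xx < W:
                                vals.append(src[yy, xx])
                out[y, x] = reduce_fn(vals)
        return out

    opened = _scan(_scan(img, min), max)
    return np.clip(img - opened, 0.0, 1.0)
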