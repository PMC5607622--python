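"""Maximum-entropy baseline detector (ImageJ-style).

Re-implements the comparison method: take the green plane of the fundus
photograph and threshold it at the gray level maximizing the Kapur
maximum-entropy criterion — the level that maximizes the sum of the
Shannon entropies of the normalized below-threshold and above-threshold
histogram classes.  Exudates are the bright class, so the detection mask
is "strictly above the threshold".

The histogram is computed within the field of view only; the near-black
camera surround would otherwise dominate the background class and drag
the threshold down.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .imgio import FundusImage, estimate_fov_mask, extract_green

__all__ = ["histogram", "max_entropy_threshold", "baseline_detect"]


def histogram(img: np.ndarray, mask: Optional[np.ndarray] = None) -> np.ndarray:
    """256-bin histogram of an intensity image on the 8-bit scale.

    Values are binned as ``round(v * 255)``.  If ``mask`` is given only
    True pixels are counted; an empty mask is an error.
    """
    img = np.asarray(img, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != img.shape:
            raise ValueError(f"mask shape {mask.shape} does not match image {img.shape}")
        if not mask.any():
            raise ValueError("histogram mask is empty")
        img = img[mask]
    levels = np.clip(np.rint(img * 255.0), 0, 255).astype(np.intp)
    return np.bincount(levels.ravel(), minlength=256)


def max_entropy_threshold(counts: np.ndarray) -> int:
    """Kapur–Sahoo–Wong maximum-entropy threshold of a 256-bin histogram.

    Returns the level ``t`` maximizing ``H_b(t) + H_f(t)``, the Shannon
    entropies (natural log, 0·log 0 := 0) of the normalized histograms
    over bins ``[0..t]`` and ``[t+1..255]``.  Candidates leaving either
    class empty are skipped; ties break toward the smallest ``t``.

    Raises
    ------
    ValueError
        If fewer than two bins are populated (no threshold can separate
        a single gray level into two classes).
    """
    counts = np.asarray(counts, dtype=np.float64)
    if counts.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(counts) < 2:
        raise ValueError("need at least two populated bins to threshold")

    total = counts.sum()
    p = counts / total
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)

    cum_p = np.cumsum(p)                 # P(class_b) for t = 0..255
    cum_plogp = np.cumsum(plogp)

    best_t, best_h = -1, -np.inf
    for t in range(256):
        pb = cum_p[t]
        pf = 1.0 - pb
        if pb <= 0.0 or pf <= 0.0:
            continue  # one class empty: criterion is -inf
        hb = np.log(pb) - cum_plogp[t] / pb
        hf = np.log(pf) - (cum_plogp[255] - cum_plogp[t]) / pf
        h = hb + hf
        if h > best_h:
            best_h, best_t = h, t
    return best_t


def baseline_detect(img: FundusImage) -> np.ndarray:
    """Green plane -> FOV-masked max-entropy threshold -> bright mask.

    The returned mask is the set of FOV pixels whose 8-bit green level is
    strictly above the Kapur threshold.
    """
    fov = img.fov_mask if img.fov_mask is not None else estimate_fov_mask(img)
    green = extract_green(img)
    t = max_entropy_threshold(histogram(green, fov))
    levels = np.clip(np.rint(green * 255.0), 0, 255).astype(np.intp)
    return (levels > t) & fov
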