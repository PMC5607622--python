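"""Outlier exclusion, area measurement, method comparison and
observer-agreement statistics.

The detector flags the optic disc and vessel-reflection outliers along
with the exudates; in the semi-automated workflow a human marks those
regions with rectangular boxes, which are applied here as scripted
:class:`ExclusionBox` records.  What remains is measured in mm² (total
and per connected component), compared between methods, and summarized
with the agreement statistics used for observer grading: the uncentered
correlation coefficient ``CC = Σ x_i y_i / sqrt(Σ x_i² Σ y_i²)``,
Bland–Altman limits of agreement, and the intraclass correlation
coefficient (two-way mixed, absolute agreement, single measure).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imgio import Calibration

logger = logging.getLogger("hequant")

__all__ = [
    "ExclusionBox",
    "load_exclusion_boxes",
    "apply_exclusions",
    "AreaReport",
    "measure_area",
    "MethodDifference",
    "compare_methods",
    "percent_detected",
    "PERCENT_BINS",
    "bin_percentages",
    "correlation_coefficient",
    "pearson_correlation",
    "BlandAltman",
    "bland_altman",
    "bland_altman_plot",
    "validate_grading_table",
    "icc_agreement",
    "AgreementStats",
    "agreement_stats",
]


# ---------------------------------------------------------------------------
# outlier exclusion

@dataclass(frozen=True)
class ExclusionBox:
    """Axis-aligned half-open rectangle ``[x0, x1) x [y0, y1)``, 0-based."""

    x0: int
    y0: int
    x1: int
    y1: int

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {self}: need x0 < x1 and y0 < y1")


def load_exclusion_boxes(path) -> list[ExclusionBox]:
    """Read exclusion boxes from CSV (header ``x0,y0,x1,y1``) or a JSON list."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        return [ExclusionBox(int(r["x0"]), int(r["y0"]), int(r["x1"]), int(r["y1"]))
                for r in records]
    df = pd.read_csv(path)
    missing = {"x0", "y0", "x1", "y1"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing exclusion-box columns {sorted(missing)}")
    return [ExclusionBox(int(r.x0), int(r.y0), int(r.x1), int(r.y1))
            for r in df.itertuples()]


def apply_exclusions(mask: np.ndarray, boxes: Sequence[ExclusionBox]) -> np.ndarray:
    """Clear every mask pixel inside any box; boxes are clipped to bounds.

    A box entirely outside the frame is ignored with a warning.  Never
    adds pixels and is idempotent.
    """
    mask = np.asarray(mask, dtype=bool).copy()
    H, W = mask.shape
    for b in boxes:
        x0, x1 = max(b.x0, 0), min(b.x1, W)
        y0, y1 = max(b.y0, 0), min(b.y1, H)
        if x0 >= x1 or y0 >= y1:
            logger.warning("exclusion box %s lies outside the %dx%d frame; ignored", b, H, W)
            continue
        mask[y0:y1, x0:x1] = False
    return mask


# ---------------------------------------------------------------------------
# area measurement

_STRUCTURES = {8: np.ones((3, 3), dtype=bool), 4: ndi.generate_binary_structure(2, 1)}


@dataclass(frozen=True)
class AreaReport:
    """Pixel and mm² areas of a detection mask, with a component breakdown."""

    pixel_count: int
    area_mm2: float
    mm_per_pixel: float
    calibration_source: str
    n_components: int
    components: tuple[tuple[int, float], ...]  # (pixel_count, area_mm2) per blob


def measure_area(mask: np.ndarray, cal: Optional[Calibration], connectivity: int = 8) -> AreaReport:
    """Measure a detection mask: total area and per-component areas.

    ``area_mm2 = pixel_count * mm_per_pixel**2``.  Components are
    8-connected by default (lesions are blob-like); pass
    ``connectivity=4`` for edge-connectivity.
    """
    if cal is None:
        raise ValueError(
            "no calibration: supply mm_per_pixel (Calibration) or derive one "
            "from the field of view"
        )
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    mm2 = cal.mm_per_pixel ** 2
    labels, n = ndi.label(mask, structure=_STRUCTURES[connectivity])
    if n:
        sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1)).astype(int)
    else:
        sizes = np.empty(0, dtype=int)
    return AreaReport(
        pixel_count=int(mask.sum()),
        area_mm2=float(mask.sum() * mm2),
        mm_per_pixel=cal.mm_per_pixel,
        calibration_source=cal.source,
        n_components=int(n),
        components=tuple((int(s), float(s * mm2)) for s in sizes),
    )


@dataclass(frozen=True)
class MethodDifference:
    """Signed area difference between methods: ``baseline - proposed``.

    A negative difference means the baseline underestimates relative to
    the proposed method.  ``ratio`` is baseline/proposed, or None when
    the proposed area is zero (flagged in ``ratio_defined``).
    """

    difference_mm2: float
    ratio: Optional[float]
    ratio_defined: bool


def compare_methods(baseline: AreaReport, proposed: AreaReport) -> MethodDifference:
    """Difference record between the baseline and proposed area reports."""
    if not np.isclose(baseline.mm_per_pixel, proposed.mm_per_pixel):
        raise ValueError(
            f"calibration mismatch: {baseline.mm_per_pixel} vs {proposed.mm_per_pixel}"
        )
    diff = baseline.area_mm2 - proposed.area_mm2
    if proposed.area_mm2 > 0:
        return MethodDifference(diff, baseline.area_mm2 / proposed.area_mm2, True)
    return MethodDifference(diff, None, False)


# ---------------------------------------------------------------------------
# percentage detection and binning

def percent_detected(mask: np.ndarray, truth: np.ndarray) -> float:
    """Percentage of ground-truth pixels covered by the detection mask."""
    mask = np.asarray(mask, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if mask.shape != truth.shape:
        raise ValueError(f"shape mismatch: {mask.shape} vs {truth.shape}")
    n_truth = truth.sum()
    if n_truth == 0:
        raise ValueError("ground-truth mask is empty: percent detected undefined")
    return 100.0 * float((mask & truth).sum()) / float(n_truth)


#: Half-open grading bins (the last is closed at 100).
PERCENT_BINS = ((0.0, 30.0), (30.0, 60.0), (60.0, 90.0), (90.0, 100.0))


def bin_percentages(values: Sequence[float]) -> tuple[int, int, int, int]:
    """Count values per grading bin: [0,30), [30,60), [60,90), [90,100]."""
    values = np.asarray(list(values), dtype=np.float64)
    if values.size and ((values < 0).any() or (values > 100).any()):
        bad = values[(values < 0) | (values > 100)][0]
        raise ValueError(f"percentage {bad} outside [0, 100]")
    edges = [30.0, 60.0, 90.0]
    idx = np.digitize(values, edges, right=False)  # 30 -> bin 1, 90 -> bin 3
    return tuple(int((idx == k).sum()) for k in range(4))


# ---------------------------------------------------------------------------
# agreement statistics

def correlation_coefficient(x: Sequence[float], y: Sequence[float]) -> float:
    """Uncentered correlation: ``Σ x_i y_i / sqrt(Σ x_i² · Σ y_i²)``.

    This is the formula used for grading validation; note it is *not*
    mean-centred (see :func:`pearson_correlation` for the centred
    variant) and is therefore close to 1 for any two positive,
    similar-magnitude series.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D series with N >= 2")
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        raise ValueError("correlation undefined: a series is all zero")
    return float(np.clip((x * y).sum() / denom, -1.0, 1.0))


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Ordinary (mean-centred) Pearson correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D series with N >= 2")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    lower_loa: float
    upper_loa: float
    means: tuple[float, ...]        # per-pair (x+y)/2, for plotting
    differences: tuple[float, ...]  # per-pair x - y


def bland_altman(x: Sequence[float], y: Sequence[float]) -> BlandAltman:
    """Bland–Altman agreement: bias and 1.96·SD limits of agreement.

    ``d = x - y``; bias is mean(d); the limits are bias ± 1.96 times the
    sample (N−1) standard deviation of d.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length 1-D series with N >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        lower_loa=bias - 1.96 * sd,
        upper_loa=bias + 1.96 * sd,
        means=tuple((x + y) / 2.0),
        differences=tuple(d),
    )


def bland_altman_plot(stats: BlandAltman, path, title: str = "Bland-Altman") -> None:
    """Write a Bland–Altman scatter with bias and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(stats.means, stats.differences, s=18, alpha=0.8)
    for yv, style, label in (
        (stats.bias, "-", f"bias {stats.bias:+.3f}"),
        (stats.lower_loa, "--", f"LoA {stats.lower_loa:+.3f}"),
        (stats.upper_loa, "--", f"LoA {stats.upper_loa:+.3f}"),
    ):
        ax.axhline(yv, linestyle=style, color="gray")
        ax.annotate(label, (0.99, yv), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference of pair")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# grading tables and ICC

_GRADING_COLUMNS = ("image_id", "grader", "session", "percent_detected")


def validate_grading_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a grading table: required columns, one row per cell, values in [0, 100]."""
    missing = set(_GRADING_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"grading table missing columns {sorted(missing)}")
    dup = table.duplicated(subset=["image_id", "grader", "session"])
    if dup.any():
        raise ValueError(
            f"duplicate (image_id, grader, session) rows: "
            f"{table.loc[dup, ['image_id', 'grader', 'session']].to_dict('records')}"
        )
    vals = table["percent_detected"].to_numpy(dtype=np.float64)
    if ((vals < 0) | (vals > 100)).any():
        raise ValueError("percent_detected outside [0, 100]")
    return table


def _paired_columns(table: pd.DataFrame, mode: str, grader: Optional[str]) -> pd.DataFrame:
    """Two ratings per image for the requested pairing.

    ``mode='intra'``: the two sessions of one grader.  ``mode='inter'``:
    grader A's session-average vs grader B's.
    """
    validate_grading_table(table)
    if mode == "intra":
        if grader is None:
            raise ValueError("intra-observer pairing needs grader=")
        sub = table[table["grader"] == grader]
        wide = sub.pivot(index="image_id", columns="session", values="percent_detected")
        wide.columns = [f"session{c}" for c in wide.columns]
    elif mode == "inter":
        means = (
            table.groupby(["image_id", "grader"])["percent_detected"].mean().unstack("grader")
        )
        wide = means
        wide.columns = [f"grader{c}" for c in wide.columns]
    else:
        raise ValueError(f"unknown pairing mode {mode!r}")
    if wide.shape[1] != 2:
        raise ValueError(f"pairing needs exactly two ratings per image, got columns {list(wide.columns)}")
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(f"incomplete design: missing cells for images {missing}")
    return wide


def icc_agreement(table: pd.DataFrame, mode: str = "intra", grader: Optional[str] = None) -> float:
    """Intraclass correlation for a grading pairing, on [-1, 1].

    Model: two-way mixed effects, absolute agreement, single measure
    (McGraw–Wong A,1 — numerically the ICC2 row of
    :func:`pingouin.intraclass_corr`).  Multiply by 100 for the
    conventional percent reporting.
    """
    import pingouin as pg

    wide = _paired_columns(table, mode, grader)
    long = wide.reset_index().melt(id_vars="image_id", var_name="rater", value_name="rating")
    try:
        res = pg.intraclass_corr(
            data=long, targets="image_id", raters="rater", ratings="rating"
        ).set_index("Type")
    except AssertionError:
        logger.warning(
            "ICC degenerate: %d image(s) is too few for the mean-squares "
            "decomposition; reporting nan", wide.shape[0],
        )
        return float("nan")
    label = "ICC(A,1)" if "ICC(A,1)" in res.index else "ICC2"
    return float(res.loc[label, "ICC"])


@dataclass(frozen=True)
class AgreementStats:
    """Bundle of agreement measures for one grading pairing."""

    cc: float
    pearson: float
    icc: float
    bland_altman: BlandAltman


def agreement_stats(table: pd.DataFrame, mode: str = "intra", grader: Optional[str] = None) -> AgreementStats:
    """CC, Pearson, ICC and Bland–Altman for one pairing of a grading table."""
    wide = _paired_columns(table, mode, grader)
    x = wide.iloc[:, 0].to_numpy(dtype=np.float64)
    y = wide.iloc[:, 1].to_numpy(dtype=np.float64)
    return AgreementStats(
        cc=correlation_coefficient(x, y),
        pearson=pearson_correlation(x, y),
        icc=icc_agreement(table, mode, grader),
        bland_altman=bland_altman(x, y),
    )
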