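"""Plan-to-image agreement: fractional thresholds, Dice, and the sweep.

The study's core analysis compares the region of the planned surface dose
above a fixed 30% threshold (A) against the Cherenkov image region above an
iterated 15-45% threshold (B), keeping the largest Dice similarity
coefficient ``DSC = 2|A n B| / (|A| + |B|)`` found over the sweep.

Reference maxima: the plan map is noiseless, so fractions refer to its raw
maximum ("max dose hotspot"); camera images are thresholded against their
99.5th-percentile value so a single hot noise pixel cannot rescale the
entire sweep.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .synthetic import CherenkovImage, DoseMap

__all__ = [
    "DEFAULT_SWEEP",
    "BinaryMask",
    "ROISpec",
    "RoiStats",
    "SweepResult",
    "dice",
    "difference_map",
    "reference_level",
    "sweep_max_dsc",
    "threshold_mask",
]

#: Image-threshold sweep: 15% to 45% in 1-percentage-point steps.
DEFAULT_SWEEP = np.arange(15, 46) / 100.0


def _grid(obj) -> np.ndarray:
    if isinstance(obj, DoseMap):
        return obj.values
    if isinstance(obj, CherenkovImage):
        return obj.values
    arr = np.asarray(obj, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D grid")
    return arr


@dataclass
class BinaryMask:
    """Thresholded region of a plan or image grid."""

    values: np.ndarray
    source: str  # {"plan", "image"}
    threshold_fraction: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be a 2-D boolean grid")

    @property
    def count(self) -> int:
        return int(self.values.sum())


def reference_level(grid, reference: str = "raw_max") -> float:
    """Reference maximum used to turn a fraction into an absolute threshold.

    ``raw_max`` is the grid maximum (noiseless dose maps); ``robust_max`` is
    the 99.5th-percentile value (camera images, robust to hot pixels).
    """
    grid = _grid(grid)
    if reference == "raw_max":
        level = float(grid.max())
    elif reference == "robust_max":
        level = float(np.percentile(grid, 99.5))
    else:
        raise ValueError("reference must be 'raw_max' or 'robust_max'")
    if level <= 0.0:
        raise ValueError("grid has no positive reference maximum")
    return level


def threshold_mask(
    grid,
    fraction: float,
    reference: str = "raw_max",
    source: str = "plan",
) -> BinaryMask:
    """Pixels at or above ``fraction`` of the reference maximum (ties in-mask)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("threshold fraction must lie in [0, 1]")
    arr = _grid(grid)
    level = reference_level(arr, reference)
    return BinaryMask(values=arr >= fraction * level, source=source, threshold_fraction=fraction)


def _mask_array(m) -> np.ndarray:
    if isinstance(m, BinaryMask):
        return m.values
    arr = np.asarray(m)
    if arr.dtype != bool:
        arr = arr.astype(bool)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    return arr


def dice(a, b) -> float:
    """Dice similarity coefficient ``2|A n B| / (|A| + |B|)``.

    Symmetric, in [0, 1].  Convention for degenerate inputs: two empty
    masks agree perfectly (1.0); exactly one empty mask gives 0.0.
    """
    a = _mask_array(a)
    b = _mask_array(b)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    na = int(a.sum())
    nb = int(b.sum())
    if na + nb == 0:
        return 1.0
    inter = int(np.logical_and(a, b).sum())
    return 2.0 * inter / (na + nb)


@dataclass
class SweepResult:
    """Dice values over the image-threshold sweep and their maximum."""

    thresholds: np.ndarray
    dsc_values: np.ndarray
    max_dsc: float
    argmax_threshold: float
    plan_fraction: float = 0.30

    def __post_init__(self) -> None:
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.dsc_values = np.asarray(self.dsc_values, dtype=float)
        if self.thresholds.shape != self.dsc_values.shape:
            raise ValueError("thresholds and dsc_values must align")

    def to_dict(self) -> dict:
        return {
            "plan_fraction": self.plan_fraction,
            "thresholds": self.thresholds.tolist(),
            "dsc_values": self.dsc_values.tolist(),
            "max_dsc": self.max_dsc,
            "argmax_threshold": self.argmax_threshold,
        }

    def write_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def write_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("threshold,dsc\n")
            for t, v in zip(self.thresholds, self.dsc_values):
                fh.write(f"{t:.6g},{v:.10g}\n")


def sweep_max_dsc(
    plan,
    image,
    plan_fraction: float = 0.30,
    thresholds=None,
) -> SweepResult:
    """Threshold-sweep maximum Dice between a plan map and a Cherenkov image.

    The plan mask is fixed at ``plan_fraction`` of the plan's raw maximum;
    the image mask is recomputed at each sweep threshold (robust reference).
    Returns every Dice value, the maximum, and the smallest threshold
    attaining it (deterministic tie-break).
    """
    if thresholds is None:
        thresholds = DEFAULT_SWEEP
    thresholds = np.sort(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise ValueError("threshold sweep is empty")
    plan_arr = _grid(plan)
    image_arr = _grid(image)
    if plan_arr.shape != image_arr.shape:
        raise ValueError(f"grid shapes differ: {plan_arr.shape} vs {image_arr.shape}")

    plan_mask = threshold_mask(plan_arr, plan_fraction, reference="raw_max", source="plan")
    level = reference_level(image_arr, "robust_max")
    dscs = np.empty_like(thresholds)
    for i, f in enumerate(thresholds):
        image_mask = image_arr >= f * level
        dscs[i] = dice(plan_mask.values, image_mask)
    best = int(np.argmax(dscs))  # first occurrence -> smallest threshold
    return SweepResult(
        thresholds=thresholds,
        dsc_values=dscs,
        max_dsc=float(dscs[best]),
        argmax_threshold=float(thresholds[best]),
        plan_fraction=plan_fraction,
    )


def difference_map(plan_mask, image_mask) -> np.ndarray:
    """Signed ternary disagreement grid.

    0 where the masks agree, +1 where only the plan mask is set, -1 where
    only the image mask is set.  The nonzero count equals
    ``|A| + |B| - 2|A n B|``.
    """
    a = _mask_array(plan_mask)
    b = _mask_array(image_mask)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return a.astype(np.int8) - b.astype(np.int8)


@dataclass
class ROISpec:
    """Rectangular region of interest, rows/cols half-open, with a label."""

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    label: str = "roi"

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("ROI must be non-empty")
        if min(self.row_start, self.col_start) < 0:
            raise ValueError("ROI must lie within the grid")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        if self.row_stop > shape[0] or self.col_stop > shape[1]:
            raise ValueError("ROI exceeds grid bounds")
        m = np.zeros(shape, dtype=bool)
        m[self.row_start : self.row_stop, self.col_start : self.col_stop] = True
        return m

    def to_dict(self) -> dict:
        return {
            "row_start": self.row_start,
            "row_stop": self.row_stop,
            "col_start": self.col_start,
            "col_stop": self.col_stop,
            "label": self.label,
        }


@dataclass(frozen=True)
class RoiStats:
    """ROI mean, population standard deviation, and reference-normalised mean."""

    mean: float
    std: float
    normalized_mean: float | None


def roi_mean_intensity(image, roi: ROISpec, reference_mean: float | None = None) -> RoiStats:
    """Average pixel value in the ROI, its std, and the mean normalised to a
    reference phantom's ROI mean (type I in the study design)."""
    arr = _grid(image)
    pixels = arr[roi.mask(arr.shape)]
    if pixels.size == 0:
        raise ValueError("ROI selects no pixels")
    mean = float(pixels.mean())
    std = float(pixels.std(ddof=0))
    if reference_mean is None:
        return RoiStats(mean=mean, std=std, normalized_mean=None)
    if reference_mean <= 0.0:
        raise ValueError("reference_mean must be > 0 when normalising")
    return RoiStats(mean=mean, std=std, normalized_mean=mean / reference_mean)
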