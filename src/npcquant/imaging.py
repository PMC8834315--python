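"""Image quantification: LSO compartment ratio and Pearson colocalization.

The LSO (lysosome-like storage organelle) compartment ratio summarizes
punctate fluorescence accumulation in a single-channel image with two
intensity thresholds: the total intensity of pixels strictly above the
high threshold, divided by the number of pixels strictly above the low
threshold (the low threshold delimits the cell-covered area).

Colocalization between two channels is the plain Pearson correlation of
paired pixel intensities, optionally restricted to a mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import (
    DegenerateFieldError,
    UndefinedCorrelationError,
    ValidationError,
)

__all__ = [
    "ThresholdPair",
    "LsoMeasurement",
    "ColocMeasurement",
    "FieldSummary",
    "lso_compartment_ratio",
    "aggregate_fields",
    "pearson_colocalization",
    "recommend_thresholds",
    "read_intensity_image",
]


@dataclass(frozen=True)
class ThresholdPair:
    """Low/high intensity thresholds with ``0 <= t_low <= t_high``."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.t_low <= self.t_high):
            raise ValidationError(
                f"thresholds must satisfy 0 <= t_low <= t_high, got "
                f"({self.t_low}, {self.t_high})"
            )


@dataclass(frozen=True)
class LsoMeasurement:
    """One field's LSO compartment ratio with its numerator and denominator."""

    ratio: float
    sum_high: float
    n_low: int
    field_id: str = ""


@dataclass(frozen=True)
class ColocMeasurement:
    """Pearson correlation over paired pixels."""

    r: float
    n_pixels: int


@dataclass(frozen=True)
class FieldSummary:
    """Per-experiment aggregate of field ratios (this mean is the replicate
    value handed to the statistics stage)."""

    mean: float
    sd: float
    n_fields: int


def _as_intensity_array(pixels, name: str = "image") -> np.ndarray:
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValidationError(f"{name} must be a non-empty 2D array, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} contains non-finite pixels")
    if np.any(arr < 0):
        raise ValidationError(f"{name} contains negative intensities")
    return arr


def _as_mask(mask, shape) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if m.shape != shape:
        raise ValidationError(f"mask shape {m.shape} != image shape {shape}")
    if not m.any():
        raise ValidationError("mask selects no pixels")
    return m


def lso_compartment_ratio(
    image,
    thresholds: ThresholdPair,
    mask=None,
    field_id: str = "",
) -> LsoMeasurement:
    """Compute the LSO compartment ratio of one field.

    Parameters
    ----------
    image:
        2D array of non-negative, finite intensities.
    thresholds:
        Low/high threshold pair.  Both comparisons are strict (``>``).
    mask:
        Optional boolean array restricting the pixels in scope.
    field_id:
        Carried through to the measurement for bookkeeping.

    Returns
    -------
    LsoMeasurement
        ``sum_high`` (total intensity of pixels > t_high), ``n_low``
        (count of pixels > t_low), and their ratio.

    Raises
    ------
    DegenerateFieldError
        If no in-scope pixel exceeds the low threshold (the ratio is
        undefined; callers should exclude and log the field).
    """
    arr = _as_intensity_array(image)
    if mask is not None:
        arr = arr[_as_mask(mask, arr.shape)]
    above_low = arr > thresholds.t_low
    n_low = int(np.count_nonzero(above_low))
    if n_low == 0:
        raise DegenerateFieldError(
            f"field {field_id!r}: no pixel above low threshold {thresholds.t_low}"
        )
    # math.fsum: correctly-rounded total, so any pixel ordering (and any
    # independent per-pixel oracle using fsum) reproduces it exactly
    sum_high = math.fsum(arr[arr > thresholds.t_high])
    return LsoMeasurement(
        ratio=sum_high / n_low, sum_high=sum_high, n_low=n_low, field_id=field_id
    )


def aggregate_fields(measurements: Sequence[LsoMeasurement]) -> FieldSummary:
    """Mean and SD of field ratios within one experiment.

    SD is the sample standard deviation (ddof=1); 0 for a single field.
    """
    if len(measurements) == 0:
        raise ValidationError("no field measurements to aggregate")
    ratios = np.array([m.ratio for m in measurements], dtype=float)
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    return FieldSummary(mean=float(ratios.mean()), sd=sd, n_fields=len(ratios))


def pearson_colocalization(ch1, ch2, mask=None) -> ColocMeasurement:
    """Pearson correlation coefficient between two intensity channels.

    Both channels must have identical shape; with a mask, only masked
    pixels enter.  No intensity thresholding is applied.

    Raises
    ------
    ValidationError
        On shape mismatch or fewer than 2 pixels in scope.
    UndefinedCorrelationError
        If either channel is constant within scope.
    """
    a = np.asarray(ch1, dtype=float)
    b = np.asarray(ch2, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"channel shapes differ: {a.shape} vs {b.shape}")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("channels contain non-finite pixels")
    if mask is not None:
        m = _as_mask(mask, a.shape)
        a, b = a[m], b[m]
    a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValidationError("need at least 2 paired pixels")
    da = a - a.mean()
    db = b - b.mean()
    ssa = float(da @ da)
    ssb = float(db @ db)
    if ssa == 0.0 or ssb == 0.0:
        raise UndefinedCorrelationError("constant channel: correlation undefined")
    r = float(da @ db) / np.sqrt(ssa * ssb)
    return ColocMeasurement(r=float(np.clip(r, -1.0, 1.0)), n_pixels=int(a.size))


def recommend_thresholds(
    image, low_percentile: float = 50.0, high_percentile: float = 99.0
) -> ThresholdPair:
    """Percentile-based threshold helper (artifact default, not a published
    protocol value): t_low at the 50th and t_high at the 99th intensity
    percentile of a control-like image unless overridden."""
    arr = _as_intensity_array(image)
    t_low = float(np.percentile(arr, low_percentile))
    t_high = float(np.percentile(arr, high_percentile))
    return ThresholdPair(t_low=t_low, t_high=max(t_low, t_high))


def read_intensity_image(path: str | Path, plane: int | None = None) -> np.ndarray:
    """Read a grayscale TIFF as a float64 intensity array.

    Multi-page files are rejected unless ``plane`` selects a page.
    Integer and 32-bit float pixel types are accepted.
    """
    import tifffile

    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if plane is None:
            raise ValidationError(
                f"{path}: multi-plane image; pass an explicit plane index"
            )
        if not (0 <= plane < arr.shape[0]):
            raise ValidationError(f"{path}: plane {plane} out of range")
        arr = arr[plane]
    elif arr.ndim != 2:
        raise ValidationError(f"{path}: expected a 2D grayscale image, got shape {arr.shape}")
    return _as_intensity_array(arr, name=str(path))
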