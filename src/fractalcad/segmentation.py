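"""Nodule/background separation by Yanni–Horne histogram thresholding.

The threshold is derived purely from the gray-level histogram: the midpoint
of the occupied gray range, Gmid = (Gmax + Gmin) / 2, is refined once to the
mean of the dominant histogram peaks on either side, Gmid' = (Gpeak1 +
Gpeak2) / 2, and the threshold is the occupied dynamic range weighted by the
cumulative probability mass up to Gmid':

    T = (Gmax - Gmin) * sum_{g = Gmin..Gmid'} p(g)

Pixels strictly above T belong to the object.  Note the formula is
proportional to the cumulative mass times the range and is *not* offset by
Gmin; the printed rule is implemented verbatim, with an opt-in
``offset_by_gmin`` mode for images whose occupied range does not start near
zero.  Gray level 0 (air in a lung CT window) is excluded when locating
Gmax/Gmin unless ``include_zero_level`` is set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateHistogramError, InvalidParameterError

__all__ = [
    "Histogram",
    "ThresholdResult",
    "compute_histogram",
    "yanni_horne_threshold",
    "binarize",
    "largest_component",
    "YanniHorneThresholder",
]

_N_LEVELS = 256


@dataclass(frozen=True)
class Histogram:
    """Gray-level counts and the empirical probability distribution p(g)."""

    counts: np.ndarray  # (256,) non-negative ints summing to M*N
    p: np.ndarray       # counts / (M*N)

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.shape != (_N_LEVELS,) or np.any(c < 0):
            raise InvalidParameterError("counts must be a (256,) non-negative array")


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    g_max: int
    g_min: int
    g_mid: float
    g_mid_prime: float
    g_peak1: int = 0
    g_peak2: int = 0

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold, "g_max": self.g_max, "g_min": self.g_min,
            "g_mid": self.g_mid, "g_mid_prime": self.g_mid_prime,
            "g_peak1": self.g_peak1, "g_peak2": self.g_peak2,
        }


def _validate_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2 or img.size == 0:
        raise InvalidParameterError("image must be a non-empty 2-D array")
    if np.any(img < 0) or np.any(img > 255):
        raise InvalidParameterError("gray values must lie in [0, 255]")
    return img.astype(np.int64, copy=False)


def compute_histogram(image: np.ndarray) -> Histogram:
    """256-bin histogram of an 8-bit image and its probability distribution."""
    img = _validate_gray(image)
    counts = np.bincount(img.ravel(), minlength=_N_LEVELS)
    return Histogram(counts=counts, p=counts / img.size)


def yanni_horne_threshold(hist: Histogram, include_zero_level: bool = False,
                          offset_by_gmin: bool = False) -> ThresholdResult:
    """Bimodal histogram threshold from the two dominant peaks.

    Peaks are the global count maxima strictly left/right of the range
    midpoint Gmid, ties broken toward the respective extreme.  Raises
    :class:`DegenerateHistogramError` when a side holds no occupied level,
    i.e. the histogram is unimodal or single-valued.
    """
    counts = hist.counts
    occupied = np.flatnonzero(counts)
    if not include_zero_level:
        occupied = occupied[occupied > 0]
    if len(occupied) < 2:
        raise DegenerateHistogramError(
            "both", "need at least two occupied gray levels")
    g_max = int(occupied.max())
    g_min = int(occupied.min())
    g_mid = (g_max + g_min) / 2.0

    left = occupied[occupied < g_mid]
    right = occupied[occupied > g_mid]
    if len(left) == 0:
        raise DegenerateHistogramError("left")
    if len(right) == 0:
        raise DegenerateHistogramError("right")
    # ties toward the extremes: leftmost on the left, rightmost on the right
    g_peak1 = int(left[np.argmax(counts[left])])
    right_rev = right[::-1]
    g_peak2 = int(right_rev[np.argmax(counts[right_rev])])
    g_mid_prime = (g_peak1 + g_peak2) / 2.0

    upper = int(np.floor(g_mid_prime))
    cum = float(hist.p[g_min:upper + 1].sum())
    threshold = (g_max - g_min) * cum
    if offset_by_gmin:
        threshold += g_min
    return ThresholdResult(threshold=float(threshold), g_max=g_max, g_min=g_min,
                           g_mid=g_mid, g_mid_prime=g_mid_prime,
                           g_peak1=g_peak1, g_peak2=g_peak2)


def binarize(image: np.ndarray, threshold: float | ThresholdResult) -> np.ndarray:
    """Object mask: 1 where the pixel value strictly exceeds the threshold."""
    t = threshold.threshold if isinstance(threshold, ThresholdResult) else float(threshold)
    if not 0.0 <= t <= 255.0:
        raise InvalidParameterError(f"threshold {t} outside [0, 255]")
    img = _validate_gray(image)
    return (img > t).astype(np.uint8)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component."""
    labels, n = ndi.label(np.asarray(mask) > 0, structure=np.ones((3, 3), int))
    if n <= 1:
        return (np.asarray(mask) > 0).astype(np.uint8)
    sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return (labels == keep).astype(np.uint8)


class YanniHorneThresholder(BaseEstimator, TransformerMixin):
    """Histogram-threshold segmenter with a scikit-learn transformer API.

    ``transform`` maps a list of 8-bit grayscale images to a list of binary
    masks.  The transform is stateless (per-image thresholds come from each
    image's own histogram); ``fit`` only validates.  Per-image
    :class:`ThresholdResult` diagnostics are kept in ``results_``.

    Parameters
    ----------
    include_zero_level : bool, default False
        Include gray level 0 when locating Gmax/Gmin.
    offset_by_gmin : bool, default False
        Add Gmin to the threshold (for occupied ranges far from zero).
    keep_largest_component : bool, default True
        Post-filter the mask to its largest 8-connected component.
    """

    def __init__(self, include_zero_level: bool = False,
                 offset_by_gmin: bool = False,
                 keep_largest_component: bool = True):
        self.include_zero_level = include_zero_level
        self.offset_by_gmin = offset_by_gmin
        self.keep_largest_component = keep_largest_component

    def fit(self, X, y=None):
        for img in X:
            _validate_gray(img)
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        results, masks = [], []
        for img in X:
            t = yanni_horne_threshold(compute_histogram(img),
                                      include_zero_level=self.include_zero_level,
                                      offset_by_gmin=self.offset_by_gmin)
            mask = binarize(img, t)
            if self.keep_largest_component:
                mask = largest_component(mask)
            results.append(t)
            masks.append(mask)
        self.results_ = results
        return masks
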