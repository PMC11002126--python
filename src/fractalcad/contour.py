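"""Contour extraction (Sobel gradient) and the centroid-anchored radial
function that feeds the spectral fractal-dimension estimator.

The Sobel kernels are applied as true convolutions (the correlation masks
are their 180-degree rotations) with reflect padding; on a binary mask the
gradient responds on a two-pixel band straddling the boundary, which is
thinned to the inner one-pixel boundary (foreground pixels with a 4-adjacent
background pixel) so the contour lies on the object itself.

The radial function samples the contour as distance-from-centroid versus
polar angle in 1-degree bins over a full turn.  For non-star-shaped
(spiculated) margins several contour points can share a bin; the outermost
intersection is kept, since spiculation is the signal of interest.  Empty
bins are filled by circular linear interpolation of adjacent magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import (EmptyRegionError, InvalidParameterError,
                         TooSmallRegionError)
from .segmentation import largest_component

__all__ = [
    "GradientField",
    "Contour",
    "RadialFunction",
    "sobel_gradient",
    "extract_contour",
    "centroid",
    "radial_function",
    "ContourExtractor",
]

# 3x3 Sobel kernels, in *convolution* orientation
SOBEL_X = np.array([[-1, 0, 1],
                    [-2, 0, 2],
                    [-1, 0, 1]], dtype=float)
SOBEL_Y = np.array([[1, 2, 1],
                    [0, 0, 0],
                    [-1, -2, -1]], dtype=float)

_CROSS = ndi.generate_binary_structure(2, 1)  # 4-connectivity


@dataclass(frozen=True)
class GradientField:
    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    orientation: np.ndarray  # radians in (-pi/2, pi/2]


@dataclass(frozen=True)
class Contour:
    """Binary contour image plus an ordered boundary trace.

    ``points`` is an (n, 2) integer array of (row, col) pixels, each set in
    ``edge_mask``; consecutive points are 8-connected when tracing succeeds.
    """

    edge_mask: np.ndarray
    points: np.ndarray

    @property
    def shape(self):
        return self.edge_mask.shape


@dataclass(frozen=True)
class RadialFunction:
    """360 contour radii r(θ), θ in whole degrees, about ``centroid``
    (1-based (Xctr, Yctr) interface coordinates)."""

    magnitudes: np.ndarray
    centroid: tuple[float, float]
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        m = np.asarray(self.magnitudes, dtype=float)
        if m.shape != (360,):
            raise InvalidParameterError("radial function must hold exactly 360 samples")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise InvalidParameterError("magnitudes must be finite and non-negative")
        object.__setattr__(self, "magnitudes", m)


def sobel_gradient(image: np.ndarray) -> GradientField:
    """Convolve with the two 3x3 Sobel kernels; return gx, gy, |G| and the
    edge orientation α = arctan(gy/gx) (α = π/2 where gx = 0, gy ≠ 0)."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise InvalidParameterError("image must be 2-D and at least 3x3")
    gx = ndi.convolve(img, SOBEL_X, mode="reflect")
    gy = ndi.convolve(img, SOBEL_Y, mode="reflect")
    mag = np.hypot(gx, gy)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.arctan(gy / gx)
    zero_gx = gx == 0
    alpha[zero_gx & (gy != 0)] = np.pi / 2
    alpha[zero_gx & (gy == 0)] = 0.0
    return GradientField(gx=gx, gy=gy, magnitude=mag, orientation=alpha)


def _moore_trace(mask: np.ndarray, max_steps: int | None = None) -> np.ndarray:
    """Moore-neighbor boundary following (clockwise, Jacob's stopping
    criterion) on a binary region; returns ordered (row, col) pixels."""
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return np.empty((0, 2), dtype=int)
    # clockwise Moore neighborhood starting west
    nbrs = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]
    start = (int(rows[0]), int(cols[0]))  # raster-order first pixel: west nbr is bg
    h, w = mask.shape

    def at(r, c):
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    trace = [start]
    prev_dir = 0  # came in looking from the west
    cur = start
    first_move = None
    max_steps = max_steps or 4 * mask.size
    for _ in range(max_steps):
        found = False
        for i in range(8):
            d = (prev_dir + i) % 8
            dr, dc = nbrs[d]
            nr, nc = cur[0] + dr, cur[1] + dc
            if at(nr, nc):
                move = (cur, (nr, nc))
                if first_move is None:
                    first_move = move
                elif move == first_move:
                    return np.array(trace[:-1] if trace[-1] == start else trace, dtype=int)
                cur = (nr, nc)
                trace.append(cur)
                # back up: restart scan from the neighbor after the backtrack
                prev_dir = (d + 5) % 8
                found = True
                break
        if not found:  # isolated pixel
            break
    return np.array(trace, dtype=int)


def extract_contour(mask: np.ndarray) -> Contour:
    """Extract the object boundary of a binary mask.

    ``edge_mask`` holds the foreground pixels on which the Sobel magnitude
    of the mask is non-zero, thinned to those with a 4-adjacent background
    pixel (the inner one-pixel boundary).  ``points`` traces the boundary of
    the largest 8-connected component in order.
    """
    m = (np.asarray(mask) > 0)
    if m.ndim != 2:
        raise InvalidParameterError("mask must be 2-D")
    n_fg = int(m.sum())
    if n_fg == 0:
        raise EmptyRegionError("mask has no foreground pixels")
    grad = sobel_gradient(m.astype(float))
    band = grad.magnitude > 1e-9
    # out-of-image treated as foreground: image borders never create edges
    inner = m & ~ndi.binary_erosion(m, structure=_CROSS, border_value=1)
    edge_mask = (band & inner).astype(np.uint8)
    n_edge = int(edge_mask.sum())
    if n_edge < 8:
        raise TooSmallRegionError(
            f"boundary has only {n_edge} pixels (< 8); region too small")
    big = largest_component(m.astype(np.uint8)) > 0
    trace = _moore_trace(big)
    keep = edge_mask[trace[:, 0], trace[:, 1]] > 0
    points = trace[keep]
    if len(points) < 8:
        raise TooSmallRegionError("traced contour shorter than 8 pixels")
    return Contour(edge_mask=edge_mask, points=points)


def centroid(region, M: int | None = None, N: int | None = None,
             mode: str = "geometric") -> tuple[float, float]:
    """Centroid (Xctr, Yctr) in 1-based coordinates.

    The default ``geometric`` mode anchors the radial sweep at the image
    center, Xctr = 1 + N/2 and Yctr = 1 + M/2, independent of the region
    content.  ``mass`` returns the foreground center of mass instead.
    """
    if isinstance(region, Contour):
        arr = region.edge_mask
    else:
        arr = np.asarray(region)
    if M is None or N is None:
        M, N = arr.shape
    if mode == "geometric":
        return (1.0 + N / 2.0, 1.0 + M / 2.0)
    if mode == "mass":
        rows, cols = np.nonzero(arr)
        if len(rows) == 0:
            raise EmptyRegionError("mass centroid of an empty region")
        return (float(cols.mean()) + 1.0, float(rows.mean()) + 1.0)
    raise InvalidParameterError(f"unknown centroid mode {mode!r}")


def radial_function(contour: Contour, center: tuple[float, float]) -> RadialFunction:
    """Sample the contour as r(θ) about ``center`` ((Xctr, Yctr), 1-based)
    in 1-degree bins.

    Bins with several contour points keep the maximum radius (outermost
    intersection); empty bins are filled by circular linear interpolation.
    A warning is recorded when more than half of the bins were empty, which
    signals a strongly non-star-shaped contour.
    """
    if len(contour.points) < 8:
        raise InvalidParameterError("contour must have at least 8 points")
    h, w = contour.edge_mask.shape
    xc, yc = float(center[0]), float(center[1])
    cc, cr = xc - 1.0, yc - 1.0  # to 0-based array coordinates
    if not (0 <= cr <= h - 1 and 0 <= cc <= w - 1):
        raise InvalidParameterError("center lies outside the image")
    pts = contour.points.astype(float)
    dy = pts[:, 0] - cr
    dx = pts[:, 1] - cc
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    dist = np.hypot(dx, dy)
    bins = np.floor(theta).astype(int) % 360
    mags = np.full(360, -1.0)
    np.maximum.at(mags, bins, dist)
    empty = mags < 0
    warnings: list[str] = []
    if empty.all():
        raise InvalidParameterError("no contour point falls in any angular bin")
    if empty.any():
        if empty.mean() > 0.5:
            warnings.append("non-star-shaped: more than 50% of angular bins empty")
        idx = np.arange(360)
        # circular linear interpolation across empty runs
        filled = idx[~empty]
        mags[empty] = np.interp(idx[empty], filled, mags[filled], period=360)
    return RadialFunction(magnitudes=mags, centroid=(xc, yc),
                          warnings=tuple(warnings))


class ContourExtractor(BaseEstimator, TransformerMixin):
    """Mask -> :class:`Contour` transformer (Sobel band, inner-boundary
    thinning, Moore trace).  Stateless; ``fit`` only validates."""

    def fit(self, X, y=None):
        self.n_features_in_ = 1
        return self

    def transform(self, X):
        return [extract_contour(m) for m in X]
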