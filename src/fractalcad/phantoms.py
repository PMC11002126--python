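"""Validation phantoms: Koch snowflake, control shapes, synthetic nodule
contours and radial profiles of prescribed spectral slope.

The phantoms play the role that physical test objects play on a scanner:
shapes whose fractal dimension is known analytically (the third-iteration
Koch snowflake, FD = log 4 / log 3 ≈ 1.2618; a straight line, FD = 1) let the
two estimators be validated without any patient data.  The synthetic nodule
generator emulates the margin types radiologists grade — smooth/lobulated
(benign-looking) versus spiculated (malignant-looking) — as star-shaped
contours r(θ) with a controllable spicule count and amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _bresenham_line
from skimage.draw import polygon as _fill_polygon

from .exceptions import InvalidParameterError

__all__ = [
    "Polyline",
    "KochSpec",
    "RasterSpec",
    "koch_snowflake",
    "rasterize",
    "synthetic_nodule_contour",
    "simulate_radial_profile",
    "make_cohort",
]


@dataclass(frozen=True)
class Polyline:
    """An ordered planar point sequence in continuous units (mm or px).

    ``vertices`` is an (n, 2) float array of (x, y) points; ``closed`` marks
    whether the last vertex connects back to the first.
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) == 0:
            raise InvalidParameterError("vertices must be a non-empty (n, 2) array")
        if self.closed and len(v) < 3:
            raise InvalidParameterError("closed polylines need at least 3 vertices")
        if np.any(np.all(np.diff(v, axis=0) == 0, axis=1)):
            raise InvalidParameterError("consecutive vertices must be distinct")
        object.__setattr__(self, "vertices", v)

    @property
    def n_segments(self) -> int:
        return len(self.vertices) if self.closed else len(self.vertices) - 1

    @property
    def length(self) -> float:
        """Total arc length, including the closing segment if closed."""
        v = self.vertices
        d = np.linalg.norm(np.diff(v, axis=0), axis=1).sum()
        if self.closed:
            d += float(np.linalg.norm(v[0] - v[-1]))
        return float(d)


@dataclass(frozen=True)
class KochSpec:
    """Parameters of the Koch snowflake phantom.

    ``side_mm`` is the side of the hexagon that bounds the first-iteration
    hexagram (the study phantom uses 20 mm); the generating equilateral
    triangle therefore has side 3 * side_mm.
    """

    iterations: int = 3
    side_mm: float = 20.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.iterations < 0 or int(self.iterations) != self.iterations:
            raise InvalidParameterError("iterations must be a non-negative integer")
        if self.side_mm <= 0:
            raise InvalidParameterError("side_mm must be positive")


@dataclass(frozen=True)
class RasterSpec:
    """Raster geometry: canvas size, physical scale and the two gray levels
    used for an anti-alias-free binary-valued rendering."""

    width_px: int = 1024
    height_px: int = 1024
    mm_per_px: float = 1.0
    foreground: int = 255
    background: int = 0

    def __post_init__(self):
        if self.width_px < 3 or self.height_px < 3:
            raise InvalidParameterError("canvas must be at least 3x3 px")
        if self.mm_per_px <= 0:
            raise InvalidParameterError("mm_per_px must be positive")
        for v in (self.foreground, self.background):
            if not 0 <= v <= 255:
                raise InvalidParameterError("intensity levels must lie in [0, 255]")

    @classmethod
    def fit(cls, shape: Polyline, width_px: int = 1024, height_px: int | None = None,
            margin_px: int = 8, **kw) -> "RasterSpec":
        """Choose ``mm_per_px`` so ``shape`` fills the canvas minus a margin."""
        height_px = width_px if height_px is None else height_px
        v = shape.vertices
        span = v.max(axis=0) - v.min(axis=0)
        avail = np.array([width_px - 1 - 2 * margin_px, height_px - 1 - 2 * margin_px])
        if np.any(avail <= 0):
            raise InvalidParameterError("margin leaves no drawable canvas")
        scale = float(np.max(span / avail))
        if scale == 0:  # degenerate point-like shape
            scale = 1.0
        return cls(width_px=width_px, height_px=height_px, mm_per_px=scale, **kw)


def _koch_subdivide(vertices: np.ndarray) -> np.ndarray:
    """One Koch step on a closed CCW polygon: each edge -> 4 edges with an
    outward equilateral bump on the middle third."""
    p = vertices
    q = np.roll(p, -1, axis=0)
    v = (q - p) / 3.0
    a = p + v
    b = p + 2.0 * v
    # outward (right of travel for a CCW polygon) = rotate the third-vector by -60 deg
    c, s = np.cos(-np.pi / 3.0), np.sin(-np.pi / 3.0)
    rot = np.column_stack([v[:, 0] * c - v[:, 1] * s, v[:, 0] * s + v[:, 1] * c])
    peak = a + rot
    out = np.empty((len(p) * 4, 2))
    out[0::4] = p
    out[1::4] = a
    out[2::4] = peak
    out[3::4] = b
    return out


def koch_snowflake(spec: KochSpec) -> Polyline:
    """Generate the Koch snowflake boundary after ``spec.iterations`` steps.

    Starts from an equilateral triangle (side ``3 * side_mm``) whose first
    iteration is the hexagram bounded by a regular hexagon of side
    ``side_mm``; iteration k has exactly 3 * 4**k segments and total length
    3 * (3 * side_mm) * (4/3)**k.  The limiting curve has FD = log4/log3.
    """
    a = 3.0 * spec.side_mm  # generating triangle side
    r = a / np.sqrt(3.0)  # circumradius
    angles = np.deg2rad([90.0, 210.0, 330.0])  # CCW, point-up triangle
    verts = np.column_stack([r * np.cos(angles), r * np.sin(angles)])
    for _ in range(int(spec.iterations)):
        verts = _koch_subdivide(verts)
    verts = verts + np.asarray(spec.center, dtype=float)
    return Polyline(verts, closed=True)


def rasterize(shape: Polyline, spec: RasterSpec, filled: bool = False) -> np.ndarray:
    """Render a polyline on a grayscale canvas, centered, with 8-connected
    1-px Bresenham segments and no anti-aliasing.

    Returns an (height_px, width_px) uint8 image holding only the two levels
    of ``spec``.  ``filled=True`` additionally fills the interior of closed
    shapes.  Raises if the scaled shape does not fit with a >= 1 px margin.
    """
    v = shape.vertices
    lo, hi = v.min(axis=0), v.max(axis=0)
    center = (lo + hi) / 2.0
    # x -> column, y -> row with the y axis pointing up on the canvas
    cols = (v[:, 0] - center[0]) / spec.mm_per_px + (spec.width_px - 1) / 2.0
    rows = (spec.height_px - 1) / 2.0 - (v[:, 1] - center[1]) / spec.mm_per_px
    rr = np.rint(rows).astype(int)
    cc = np.rint(cols).astype(int)
    if (rr.min() < 1 or cc.min() < 1 or rr.max() > spec.height_px - 2
            or cc.max() > spec.width_px - 2):
        raise InvalidParameterError(
            "shape exceeds the canvas (a >= 1 px margin is required); "
            "reduce mm_per_px or enlarge the canvas")
    img = np.full((spec.height_px, spec.width_px), spec.background, dtype=np.uint8)
    if filled and shape.closed:
        fr, fc = _fill_polygon(rr, cc, shape=img.shape)
        img[fr, fc] = spec.foreground
    n = len(rr)
    last = n if shape.closed else n - 1
    for i in range(last):
        j = (i + 1) % n
        lr, lc = _bresenham_line(rr[i], cc[i], rr[j], cc[j])
        img[lr, lc] = spec.foreground
    return img


def synthetic_nodule_contour(base_radius_px: float, n_spicules: int,
                             spicule_amplitude: float, seed: int,
                             n_points: int = 720) -> Polyline:
    """Star-shaped synthetic nodule margin r(θ) = R + A·perturbation(θ).

    The perturbation mixes a dominant ``n_spicules``-cycle sinusoid (the
    regularly spaced spicules) with seeded band-limited harmonic roughness,
    normalised so its extreme value is 1; ``spicule_amplitude`` is therefore
    the peak radial excursion in px.  ``amplitude = 0`` yields an exact
    circle; a fixed seed makes the contour reproducible.
    """
    if base_radius_px <= 0:
        raise InvalidParameterError("base_radius_px must be positive")
    if n_spicules < 0 or int(n_spicules) != n_spicules:
        raise InvalidParameterError("n_spicules must be a non-negative integer")
    if spicule_amplitude < 0:
        raise InvalidParameterError("spicule_amplitude must be non-negative")
    if spicule_amplitude >= base_radius_px:
        raise InvalidParameterError(
            "spicule_amplitude must be smaller than base_radius_px "
            "(self-intersection risk)")
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    if spicule_amplitude == 0:
        r = np.full(n_points, float(base_radius_px))
    else:
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        pert = np.zeros(n_points)
        w_spike, w_rough = 0.75, 0.25
        if n_spicules > 0:
            pert += w_spike * np.cos(n_spicules * theta + phase)
        else:
            w_rough = 1.0
        # band-limited 1/k roughness above the spicule frequency; the band
        # widens with the spicule count (complex margins are rough at finer
        # angular scales than lobulated ones)
        k_lo = max(2, n_spicules + 1)
        k_hi = max(k_lo + 4, 4 * n_spicules) if n_spicules > 0 else 16
        rough = np.zeros(n_points)
        for k in range(k_lo, k_hi + 1):
            rough += (1.0 / k) * np.cos(k * theta + rng.uniform(0.0, 2.0 * np.pi))
        peak = np.max(np.abs(rough))
        if peak > 0:
            pert += w_rough * rough / peak
        pert /= np.max(np.abs(pert))
        r = base_radius_px + spicule_amplitude * pert
    verts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return Polyline(verts, closed=True)


def simulate_radial_profile(beta: float, n: int, seed: int) -> np.ndarray:
    """Random radial profile whose expected one-sided power spectrum is
    proportional to frequency**beta (beta <= 0).

    Built by inverse FFT of Fourier amplitudes |k|**(beta/2) with uniform
    random phases (spectral synthesis); the result is shifted so every
    sample is positive, which only changes the DC term.  Returns an
    n-sample float array.
    """
    if beta > 0:
        raise InvalidParameterError("beta must be <= 0 (red or white spectra only)")
    if n < 16 or n % 2 != 0:
        raise InvalidParameterError("n must be an even integer >= 16")
    rng = np.random.default_rng(seed)
    half = n // 2
    k = np.arange(1, half + 1, dtype=float)
    amp = k ** (beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, half)
    spectrum = np.zeros(n, dtype=complex)
    spectrum[1:half + 1] = amp * np.exp(1j * phases)
    spectrum[half] = amp[-1] * np.cos(phases[-1])  # Nyquist bin must be real
    spectrum[half + 1:] = np.conj(spectrum[1:half][::-1])
    profile = np.fft.ifft(spectrum).real * n
    profile = profile - profile.min() + 1.0
    if not np.all(np.isfinite(profile)):
        raise InvalidParameterError("non-finite profile generated")
    return profile


def make_cohort(n_smooth: int = 20, n_spiculated: int = 20, seed: int = 0,
                base_radius_px: float = 50.0, canvas_px: int = 256):
    """Generate a labelled synthetic cohort of rasterized nodule images.

    Smooth (probably benign) nodules are mildly lobulated: 2-4 lobes, peak
    excursion 6-10 % of the radius.  Spiculated (probably malignant) nodules
    carry 8-14 spicules with peak excursion 30-40 % of the radius, the
    margin type with the highest predictive value for malignancy.

    Returns ``(images, labels)`` with labels 'low'/'high'.
    """
    rng = np.random.default_rng(seed)
    spec = RasterSpec(width_px=canvas_px, height_px=canvas_px, mm_per_px=1.0)
    images, labels = [], []
    for _ in range(n_smooth):
        amp = base_radius_px * rng.uniform(0.06, 0.10)
        shape = synthetic_nodule_contour(base_radius_px, int(rng.integers(2, 5)),
                                         amp, int(rng.integers(0, 2 ** 31)))
        images.append(rasterize(shape, spec, filled=True))
        labels.append("low")
    for _ in range(n_spiculated):
        amp = base_radius_px * rng.uniform(0.30, 0.40)
        shape = synthetic_nodule_contour(base_radius_px, int(rng.integers(8, 15)),
                                         amp, int(rng.integers(0, 2 ** 31)))
        images.append(rasterize(shape, spec, filled=True))
        labels.append("high")
    return images, labels
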