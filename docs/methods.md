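# Methods

## Problem and model

A lung nodule's margin type is among the strongest imaging predictors of
malignancy: smooth, well-defined edges are mostly benign; spiculated,
irregular or lobulated margins are mostly malignant. Treating the margin as
a planar curve, its fractal dimension (FD) — how the measured detail grows
as the measuring scale shrinks — places it on a continuum from FD = 1
(rectifiable, smooth) to FD = 2 (plane-filling). The package estimates the
contour FD of a segmented nodule with two estimators and thresholds it into
a two-class call (low/high malignancy suspicion).

Assumptions: a single nodule per analyzed image (or per region of
interest); an 8-bit grayscale slice whose histogram is bimodal
(nodule vs. background) so a global threshold separates them; a contour that
is approximately star-shaped about the image center, so the radial function
r(θ) is well defined (violations are handled by the outermost-intersection
rule and flagged).

## Pipeline stages and their parameters

### Histogram thresholding (Yanni–Horne)

With p(g) the gray-level probability distribution, Gmax/Gmin the
highest/lowest occupied levels, Gmid = (Gmax+Gmin)/2, and Gpeak1/Gpeak2 the
count maxima strictly left/right of Gmid (ties broken toward the extremes),
one refinement gives Gmid′ = (Gpeak1+Gpeak2)/2 and

    T = (Gmax − Gmin) · Σ_{g=Gmin..⌊Gmid′⌋} p(g).

Pixels strictly above T are object. Choices made where the rule is
ambiguous:

* Gray level 0 is excluded when locating Gmax/Gmin (`include_zero_level`
  restores it): in a lung window the air background maps to 0 and would
  otherwise pin Gmin.
* The formula is implemented verbatim. It is proportional to the occupied
  range times the cumulative mass and is *not* offset into the range; for
  two equal impulses at 100 and 102 it returns T = 1, below both. An
  opt-in `offset_by_gmin` mode adds Gmin for images whose occupied range
  starts far from zero. The verbatim form is the tested default.
* One refinement pass only; the update is not iterated to a fixed point.
* The mask is post-filtered to its largest 8-connected component
  (`keep_largest_component`, default on) to drop stray specks.

### Contour extraction (Sobel)

The two 3×3 Sobel kernels are applied as true convolutions (so the
correlation masks are their 180° rotations) with reflect padding; borders
never create edges. |G| = √(gx²+gy²); α = arctan(gy/gx) with α = π/2 where
gx = 0, gy ≠ 0 and α = 0 where both vanish. On a binary mask the response
is a two-pixel band straddling the boundary; it is thinned to the *inner*
boundary — foreground pixels with a 4-adjacent background pixel — because a
two-pixel-thick band biases FD upward. The ordered trace (Moore
neighborhood, Jacob's stopping criterion) follows the largest component.

### Radial function

r(θ) is sampled in 360 one-degree bins about the centroid. The default
centroid is the geometric image center in 1-based coordinates,
Xctr = 1 + N/2, Yctr = 1 + M/2 (`centroid_mode="mass"` uses the foreground
center of mass; for a nodule cropped to its bounding box the two nearly
coincide). Bins holding several contour points keep the maximum radius:
spiculation is the signal of interest, so the outermost intersection is
retained. Empty bins are filled by circular linear interpolation; when more
than half the bins are empty the contour is flagged non-star-shaped in the
result metadata.

### Box counting

Box sizes start at min(M, N) and halve (integer floor) down to 2 px, the
pixel spacing; the grid is anchored at the image origin. K(r) is the number
of grid cells holding ≥ 1 contour pixel, and FD is the least-squares slope
of log K(r) on log(1/r).

Only the scaling band of the series enters the fit. Three documented drop
rules, each a parameter, exclude scales that carry no fractal signal:

* **saturation** (`drop_saturated`): scales where K(r) equals the
  foreground pixel count — every box resolves a single pixel;
* **hull regime** (`hull_factor`, default 2): scales r > extent/2, where
  extent is the longer side of the foreground bounding box — a handful of
  boxes cover the whole object and the count scales like its convex hull
  (local slope → 2);
* **digitized-line regime** (`fine_factor`, default 16): scales
  r < extent/16 — below the inner cutoff of a finite-resolution contour the
  curve decomposes into straight pixel runs (local slope → 1).

On the iteration-3 Koch snowflake outline at a 1024 px canvas the full
dyadic ladder mixes all three regimes and underestimates by ≈ 7 %; the
scaling-band fit recovers the theoretical 1.2618 to < 0.1 %. Fewer than
three usable scales raises an error rather than returning a two-point
slope. `grid_offsets = n` averages K(r) over n seeded random grid offsets —
useful to suppress grid-phase (lacunarity) noise when comparing nearby
shapes — and is off by default (a single anchored grid).

### Power spectrum

The mean-removed radial function is Fourier-transformed (unnormalized DFT);
the one-sided power P(k) = |F(k)|², k = 1..180, excludes DC (mean removal
makes that exclusion well defined). ß is the least-squares slope of
log P(k) on log k over the fit band, and

    FD = (4 + ß)/2,

so a Brownian-like ß = −2 gives FD = 1 and a white ß = 0 gives FD = 2. The
classical 1-D profile relation FD = (5 − β)/2 (β = −ß) is available as
`relation="classical"` for sensitivity analysis, and the literal reading
(log |F|)² of the ordinate as `literal_squared_log` — it is not
scale-invariant (rescaling r(θ) changes its slope), which is why log-power
is the default reading.

**Fit band.** Default k ∈ [1, 30]. The upper harmonics of a 360-sample
digitized radial function sit on a flat pixel-quantization noise floor
(radii are known only to ≈ ±0.5 px); ordinary least squares over the full
one-sided band is dominated by that floor and drags every smooth contour
toward ß ≈ 0, i.e. FD ≈ 2. Restricting the fit to the first 30 harmonics —
the band where nodule-scale structure (lobes and spicules at 2–25 cycles
per revolution) lives — keeps the shape-driven decay. The band is a
configuration knob (`fit_band`).

An all-zero spectrum (a perfect circle) raises a degenerate-spectrum error;
the pipeline maps it to the smooth-shape fallback FD = 1.

### Classification and evaluation

FD strictly above the method cut-off (1.214 box counting, 1.137 power
spectrum, both configurable) is called *high*. Radiologist annotations
(1–4 votes, each 1–5) reduce to the most repeated value; ties break toward
the higher grade (clinically conservative; `tie_break` also offers `low`
and `mean-round`). Grades 1–3 are the low class, 4–5 high.
Sensitivity/specificity/accuracy follow the standard confusion-count
definitions, stored as fractions; the percent rendering truncates to one
decimal, matching the convention of the published tables this mirrors
(93.75 % prints as 93.7). Pearson correlation between FD and consensus
grade uses the sample product-moment coefficient.

## Synthetic data

`synthetic_nodule_contour` builds star-shaped margins
r(θ) = R + A·perturbation(θ): a dominant n-spicule sinusoid (weight 0.75)
plus seeded 1/k harmonic roughness on k ∈ (n, 4n] (weight 0.25), normalized
so A is the peak radial excursion in px. A = 0 is an exact circle; the
roughness band widens with the spicule count, emulating the finer-scale
irregularity of complex margins. `make_cohort` freezes the two study
classes: *smooth* = 2–4 lobes, A = 6–10 % of R; *spiculated* = 8–14
spicules, A = 30–40 % of R; R = 50 px on a 256 px canvas, CT-like scale for
a 25 mm nodule at ~0.5 mm/px.

What the generator does *not* emulate: CT noise and texture (the phantom
images are two-level), partial-volume blur at the margin, non-star-shaped
lesions, vessels or pleural attachments that survive segmentation, and 3-D
effects of slice selection. Passing cohort tests therefore demonstrate the
geometry → FD → classification chain under clean segmentation, not
robustness to scanner physics; the segmentation stage is exercised
separately on two-level and CT-like-bimodal images.

`simulate_radial_profile` synthesizes profiles with power-law spectra by
inverse FFT of amplitudes |k|^(β/2) with seeded uniform random phases
(deterministic amplitudes, so the fitted slope recovers β exactly up to the
Nyquist bin); it validates the spectral estimator independently of any
contour.

## Numerical choices

* Least-squares fits use `numpy.polyfit` degree 1; slope and intercept are
  asserted against the closed-form normal equations in the tests; r² is
  clipped to [0, 1].
* Raw FD values are preserved; a clamped copy in [1, 2] is reported with a
  warning when clamping occurred, and a warning flags fits with r² < 0.95.
* Internal arrays are 0-based row-major; the 1-based (Xctr, Yctr)
  convention is honored at the interface and converted exactly once
  (`"coordinate_convention": "1-based at interface"` in result JSON).
* Rasterization is anti-alias-free: 8-connected Bresenham segments,
  optional scan-line interior fill; identical inputs give identical images.
* Histogram peak ties break toward the extremes (maximal peak separation);
  binarization is strictly greater-than; cut-off comparisons are strictly
  greater-than ("greater than" boundaries classify as low).
* All randomness flows through `numpy.random.default_rng(seed)` with
  explicit seeds; nothing reads global RNG state.

## Known limitations

* **Deterministic symmetric phantoms break the spectral estimator.** The
  Koch snowflake's radial function is deterministic with 6-fold symmetry:
  its spectrum is a line spectrum at k = 6m riding on the quantization
  floor, not a power law. A full-band fit returns the floor slope (FD ≈
  1.9); fitting only the line harmonics returns their decay (ß ≈ −2.2,
  FD ≈ 0.9 under the (4+ß)/2 relation — consistent with the classical
  graph-dimension relation, for which a D ≈ 1.26 curve implies β ≈ 2.5).
  No fit convention recovers 1.2618 from this phantom, so the spectral
  estimator is validated on stochastic power-law profiles instead; the
  box-counting estimator is the one validated on the Koch phantom.
* The (4+ß)/2 relation differs from the classical (5−β)/2 profile
  relation; it is kept as the primary mapping for comparability, with the
  classical form one flag away.
* Box-counting estimates at a fixed raster resolution depend on that
  resolution (the scaling band spans at most a few octaves); FD values
  from different pixel scales should not be compared without care.
* The fixed cut-offs (1.214/1.137) come from one study population and one
  scanner resolution; they are defaults, not universal constants.
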