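# Methods

## The segmentation criterion

The algorithm treats threshold selection as a spatial-statistics problem.
For a preprocessed grey image F ∈ [0,1] and a candidate level l, the
binarization operator marks pixels with F > l (strictly) as foreground.
Connected components (8-connectivity by default) give regions with areas
r = [r₁ … r_nR]; the median absolute deviation filter

    MAD = b · median(|r − median(r)|),   b = 1.4826

keeps region i iff |r_i − median(r)| / MAD < 3, discarding area outliers
robustly (the median-based statistic is insensitive to a minority of
aberrant regions). When MAD = 0 — identical areas, or a single region —
every region is kept: equal areas carry no outlier evidence. Centroids are
first-order moments (M10/M00, M01/M00) of each inlier region's pixel
coordinates, sub-pixel, in (x = column, y = row) coordinates with a
top-left origin.

The inlier centroids are Delaunay-triangulated (every triangle's
circumcircle is empty of other vertices). Each triangle contributes its
three edge lengths to the distance vector d of length 3n, so an edge
shared by two triangles is counted once per triangle; a config switch
(`unique_edges`) collapses duplicates for sensitivity analysis. The
lengths are binned into a histogram of width w (default 1 px) over
[0, max d + w), normalized to occurrence probabilities p(d|l).

The ideal model is the Rayleigh density ℛ(d|σ) = (d/σ²)·exp(−d²/2σ²) —
the exact nearest-neighbour distance law of a homogeneous Poisson process
with intensity λ, with σ = 1/√(2πλ). To compare a continuous density with
discrete frequencies on equal terms, the Rayleigh is converted to a
per-bin probability mass by CDF differences across the bin edges, and

    RMSD(σ, l) = sqrt( mean_bins ( R_mass(bin|σ) − p(bin|l) )² ).

This choice makes RMSD = 0 attainable exactly when the histogram equals
the binned Rayleigh mass, and makes the objective dimensionless. σ is fit
by grid search (ties toward smaller σ), and the reported segmentation is
the level minimizing the fitted RMSD (ties toward smaller l). Levels that
yield fewer than three usable centroids, or a collinear set, are marked
invalid (RMSD = +∞) rather than aborting the scan; only if every level is
invalid does the scan raise a diagnostic error.

## Preprocessing

F = rescale( P_S ⊘ (M(∂_t P_R) + ε) ): Perona-Malik diffusion of the red
channel, mean-shift quantization M of the result, and elementwise division
of the original image's HSV saturation channel by it, min-max rescaled to
[0,1] so the level scan always runs on a fixed domain. A constant ratio
(range below 1e−9) maps to an all-zero image — this covers the pure-grey
input whose saturation is identically zero.

* **Perona-Malik** uses the explicit 4-neighbour scheme with reflecting
  boundaries, which conserves the image mean exactly at each step, and is
  stable for step ≤ 0.25. Defaults: 10 iterations, step 0.2, contrast
  κ = 0.1 on [0,1] intensities, exponential edge-stopping function
  exp(−(|∇|/κ)²); the rational form 1/(1+(|∇|/κ)²) is selectable. These
  are conventional values for unit-scaled images; all are config-exposed.
* **Mean shift** operates on the 1-D intensity distribution only
  (range-only), with a flat kernel of bandwidth 0.1: each intensity climbs
  to a mode of the count-weighted sample; converged modes closer than the
  bandwidth are merged by weighted means until all survivors are separated
  by more than the bandwidth. This termination rule makes the operator
  exactly idempotent. Images with more than 512 distinct values are first
  summarized by count-weighted histogram representatives, which bounds the
  cost on float images without affecting the few-valued output path.
* **Hadamard division** adds ε = 1e−6 to the denominator so the ratio is
  always finite.

## Default grids

The level grid is l ∈ {0.01, …, 0.99} in steps of 0.01 — a percent-indexed
traversal of the unit interval. The default σ grid is 0.5–150 px in steps
of 0.5: the Rayleigh scale of a point pattern is tied to its density
(σ ≈ 1/√(2πλ) for the nearest-neighbour law; the mean Delaunay edge is
≈ 1.13/√λ), and a ceiling of a few tens of pixels would exclude
legitimately sparse patterns. Both grids, the histogram bin width, the MAD
constants, the connectivity, the minimum region area (speckle floor,
default 4 px), border-region handling and the polarity flag are set in the
config block.

For the synthetic fixtures (λ = 4e−4 points/px², blobs of ~200–280 px) the
generator provides a matched analysis config (`preset_scan_config()`):
σ ∈ [20, 150] px and a minimum area of 30 px. These are physical priors at
that scale — centers closer than ~20 px cannot be distinct stomata whose
rendered bodies are ~16 px across, and regions under 30 px are an order of
magnitude smaller than the smallest rendered stoma. Without such priors
the scan can be captured by threshold levels at which background noise
crossings form dense point patterns: near-critical percolation clusters of
a noisy background are themselves approximately Poisson-distributed, fit a
Rayleigh well, and — because finer histograms reward larger edge counts —
can outscore the true, sparser stomatal pattern. Declaring the plausible
spacing range is the documented way to run the tool at a known imaging
scale; the generic defaults remain neutral.

## Synthetic data

`sample_poisson_points` draws a homogeneous Poisson pattern (count ~
Poisson(λ·area), uniform positions), optionally thinned to a hard-core
process: points are visited in generation order and rejected when closer
than `min_separation` to an already accepted point. Pure Poisson is the
default because the Rayleigh nearest-neighbour law is exact there, giving
the closed-form oracle σ = 1/√(2πλ) used in calibration tests; the
hard-core option emulates the one-cell-spacing rule of stomatal
development. A border margin keeps blobs fully on canvas.

`render_stomata_image` draws one ellipse per point (semi-axes 7–8.5 ×
4.5–5.5 px, random orientation) with a saturated green interior
(RGB 0.20/0.55/0.28), a darker rim, on a low-saturation brownish
background (0.55/0.50/0.44), modulated by a smooth multiplicative
illumination field (correlation length 50 px, relative sd 0.01 —
multiplicative so that, like real shading, it cancels in the saturation
channel), then Gaussian defocus blur and additive sensor noise. Presets:

* `clean` — defocus 0.8 px, no sensor noise, identical blob colors: an
  ideal-imaging control on which the chain should recover essentially all
  planted centers.
* `noisy` — sensor noise sd 0.02, per-blob color jitter, stronger
  illumination texture.
* `defocus` — blur sd 6 px, comparable to the blob minor radius, the
  out-of-focus failure mode that degrades edge-based segmentation.

What the generator does *not* emulate: epidermal cell walls and texture at
the stomatal scale, chromatic aberration and demosaic artifacts, stain
variability, biologically realistic guard-cell morphology, and the
developmental correlations of real stomatal patterns beyond a hard-core
radius. A passing suite therefore shows the chain is correct and robust
under controlled spacing statistics, not that any particular accuracy
carries over to a given real dataset; expect real micrographs to behave
between the `clean` and `defocus` extremes.

The planted-band fixture (`planted_band_image`) is a grey image whose
background (mid-grey plus clipped smooth texture) stays strictly below
0.55 and whose blob interiors lie strictly above 0.65, so thresholds
inside (0.55, 0.65) segment exactly the planted blobs; it pins down the
scan's ability to land in a known separability band.

## Evaluation protocol

Predictions are matched to annotated centers one-to-one, greedily by
ascending Euclidean distance, with pairs admitted below a radius
(default 30 px, always reported alongside the metrics, since the choice is
scale-dependent). Unmatched annotations are false negatives and unmatched
predictions false positives; PPV = TP/(TP+FP), TPR = TP/(TP+FN). A zero
denominator yields an undefined (null) metric rather than zero, so
aggregate means are not silently deflated; aggregates report mean ± sd
over the images where the metric is defined. Greedy matching is optimal
whenever annotations are separated by more than twice the radius (each
prediction then has at most one candidate) and is never worse than half
the optimal assignment in general — the suite checks both properties
against an exhaustive-enumeration oracle.

## Numerical and engineering choices

* Binarization is strict (F > l); a pixel exactly at the level is
  background.
* Cocircular point sets make the Delaunay triangulation non-unique; either
  diagonal is accepted, and the geometric tests use points in general
  position.
* The scan, given identical inputs and configuration, is fully
  deterministic; the CLI records a config hash and seed in the summary,
  and repeated runs are byte-identical.
* Synthetic images are written as 16-bit TIFF: 8-bit quantization of
  near-uniform blob peaks creates artificial intensity plateaus that
  perturb threshold selection, and 16-bit depth is standard for microscopy
  exports anyway. 8-bit input remains fully supported.
* Problem sizes in the test suite and acceptance script — 700²–1000²
  canvases, ~100–150 planted stomata per image, 20 replicates for the
  statistical checks — were chosen as the smallest sizes at which the
  spatial statistics are stable (the Rayleigh fit needs on the order of a
  hundred points to constrain σ; the paper-scale regime of a few hundred
  regions per image behaves the same).

## Known limitations

* The objective rewards any point pattern that is Poisson-like at a
  density the σ grid can express; on very noisy images the MAD filter and
  area floor are the only guards against noise-cluster patterns, so the σ
  and area priors should be set from the imaging scale (see above).
* The RMSD objective has a mild preference for thinned (more
  Poisson-like) subsets of strongly regular patterns, which can bias the
  selected level upward when blob intensities vary; this is inherent to
  measuring distance to a Rayleigh ideal.
* Range-only mean shift ignores spatial coherence; joint spatial-range
  mean shift is out of scope.
* The evaluation is purely center-distance based; no area-overlap (IoU)
  scoring.
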