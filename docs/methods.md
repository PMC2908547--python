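# Methods

This note documents the models, numerics and design choices behind the
package, and what the synthetic tests do and do not demonstrate.

## One-shot appearance learning

Both the worm and the background are described by mixtures of multivariate
Gaussians over vectorized ρ×ρ intensity patches, all learned from a single
annotated frame (mask + worm width).  Patches carry local texture that
single pixels do not; with ρ = 1 the model reduces exactly to per-pixel
intensity mixtures (this limit is asserted in the tests).

**Patch size.**  ρ = round(a·w + b) from the annotated width w, coerced to
the nearest odd integer and capped at a quarter of the image side.
Defaults a = 0.25, b = 0.5 give ρ = 3 for a typical 9–10 px wide adult
worm.  The linear constants are free parameters; nothing in the method
depends on their exact values, only on ρ growing with the worm scale.

**Worm model.**  N = 2000 patch centers are drawn uniformly from the mask
(with replacement when the mask is smaller than N).  Default K = 3
components.  Two components capture the worm's two-tone body (dark
muscle ≈ 55, brighter gut ≈ 85 in the generator); the third captures
boundary patches that mix worm and background pixels.  With only K = 2 those
mixed patches are claimed by neither model and the segmented worm loses its
1-px boundary ring in low-contrast scenes, which is why the default is 3.

**Background model.**  The image is tiled into non-overlapping cells
(default 32×32 px; edge cells take the remainder) and each cell gets its
own K = 3 mixture, fitted on every patch whose center lies outside the worm
mask.  Local models absorb illumination gradients and static structures
(each cell containing pillars learns a pillar component).  A cell fully
covered by the worm inherits the model of the nearest cell with admissible
samples — the operating assumption is that occluded background looks like
its neighborhood, which requires background structure to repeat at the
cell scale (the synthetic pillar lattice is denser than the cell size for
exactly this reason; a scene whose occluded structure is unique would
violate the assumption).

**EM numerics.**  k-means++ seeding, hard initial assignment, then standard
EM with full covariances; covariance eigenvalues are floored at
1e-4·(255)² ≈ 6.5 so degenerate clusters stay positive definite; the fit
stops when the relative log-likelihood gain drops below 1e-6 or after 200
iterations.  The log-likelihood trajectory is stored on the model and the
tests assert its monotonicity on every fit.  If K exceeds the number of
distinct samples, K is reduced with a warning.  All randomness is seeded;
fits are bit-reproducible.

## Likelihood-ratio segmentation

Each pixel is scored by p(patch | M_W) / p(patch | M_BG,cell), computed in
log space with the background density floored at 1e-300 so the ratio is
always finite.  The decision threshold is τ = 1 — the plain likelihood-
ratio rule; because both classes are explicitly modeled there is no
intensity threshold to tune.  Patches are taken centered at every pixel
(overlapping), with edge replication at the border so every pixel is
classifiable.

**Smoothing.**  Morphological closing then opening with a disk of radius
max(1, round(w/4)), then (by default) retention of the largest connected
component.  Closing runs first deliberately: where the worm boundary is
ambiguous the raw decision map has thin gaps along the boundary, which
closing bridges; opening first would erode those half-detected runs and
systematically thin the worm.  Isolated false-positive specks that closing
cannot create are removed by the largest-component filter.

**Known bias.**  A patch centered just outside the worm still contains worm
pixels, and such patches have essentially zero density under any
background cell model, so the segmented worm is dilated outward by about
ρ//2 ≈ 1 px.  This is inherent to overlapping-patch classification: it
inflates the mask boundary (visible as per-frame Jaccard ≈ 0.8 against
exact ground truth even when the worm yield is ≈ 1.0) but does not affect
the midline, and therefore none of the motility metrics.

**Threshold baseline.**  For comparison studies the package includes the
classic recipe: per-pixel mean over all frames as the background image,
absolute background subtraction, a difference threshold, the same
morphology, largest component.  The threshold is tuned automatically on
the annotated frame (maximizing Jaccard against the hand mask over a
quantile sweep), emulating a user iterating on the initial image.  With a
single input frame, background subtraction is skipped and an intensity
band from the annotated worm pixels is used instead.

## Midline tracing

The mask's exact Euclidean distance transform D is zero on the background
and maximal near the medial axis.  (The exact transform is used rather
than an integer chamfer approximation; exactness makes the brute-force
oracle test sharp.)

Tracing is sequential Bayesian estimation over the 8 unit directions V:

* start: the strongest maximum of a Harris corner response computed on the
  mask smoothed with σ = w/2 ("coarse", so only body ends respond).  The
  two strongest well-separated maxima are the end candidates; no head/tail
  identity is assigned.  A shape whose response is spatially diffuse (a
  disk has corners everywhere) triggers a degenerate-shape warning.
* step: likelihood(v) ∝ D(x_k + v)^γ (γ = 1 by default); the next point is
  argmax over v of likelihood × prior, ties broken by smallest angular
  deviation from the previous direction, then by enumeration order.
* history: the direction distribution is updated by Bayes' rule.  The
  update tempers the prior as P^β (β = 0.6) before multiplying in the new
  likelihood — exponential forgetting with an effective memory of ~2.5
  steps.  An exact product of all past likelihoods concentrates
  geometrically and cannot follow body bends; β controls the noise-damping
  vs. flexibility trade-off and β = 1 restores the pure product.
* termination: visited pixels are zeroed on a working copy of D, so the
  walk cannot backtrack; it stops when every candidate is background, with
  a hard cap of mask-area steps.

Masks enclosing a large hole (coiled worm, omega bend with touching ends)
are rejected with an explicit unsupported-posture error: the medial axis
of an annulus has no endpoints and the corner initialization is ill-posed.

A walk can occasionally dead-end mid-body on a noisy, strongly bent mask
(it cuts the inside of the bend and traps itself against its own visited
trail).  `extract_skeleton` therefore compares the walk's length with the
length the mask area implies (area / width) and, when the walk falls below
70% of it, retries from the other endpoint candidate and then with
progressively shorter history memory (decay 0.4, then 0.25); the first
adequate walk wins and the longest seen is the last resort.  Walks are
*not* simply compared by length: preferring the longest walk
systematically selects wigglier paths and biases the wavelength estimate.

A traced 8-connected path zigzags at the pixel scale and over-measures arc
length by ~20%.  `postprocess_skeleton` turns the raw path into the
analysis midline: moving-average de-zigzag (`smooth_path`, window 7,
endpoints fixed), arc-length-uniform resampling, then a Gaussian pass over
the resampled coordinates (sigma 2.5 sample spacings) and a final
resampling.  The Gaussian pass is quantitatively important: the ~5%
residual wiggle left by the moving average inflates the measured body
length, which deflates wavelength-type metrics by the same factor (the
wave's phase ramp gets spread over an inflated arc coordinate); after the
pass the midline length is within ~1–3% of truth and the recovered
wavelength within ~4%.  The trace spans the tube tip to tip, so its length
slightly exceeds the true midline's; real imagery errs the other way
(transparent head/tail truncate the skeleton), which is why the tests
assert a lower bound on arc recovery rather than a two-sided band.

## Motility metrics

Skeletons are resampled to n = 51 points equally spaced in arc length;
frame-to-frame orientation is enforced by flipping any skeleton whose
reversed order better matches the previous frame, so s = 0 stays on one
consistent end (which physical end it is remains unknown).

**Curvature.**  κ = dφ/ds with φ the unwrapped tangent angle.  Coordinates
are Gaussian-smoothed along the body (σ = 1.5 sample spacings) and φ and κ
are taken by centered differences on the cumulative arc length.  A
smoothing-spline parametric fit was tried first and rejected: with any
nonzero smoothing `splprep` distorted interior curvature by tens of
percent and overshot at the ends, biasing the wavelength estimate by ~30%;
the finite-difference estimator reproduces analytic circle and sine
curvature to better than 5% on interior points and the traveling-wave
wavelength to 0.1% on exact midlines.

**Frequency.**  Each interior body position (s ∈ [0.2, 0.8]) contributes
the frequency of the dominant bin of its mean-detrended, Hann-windowed
power spectrum (DC excluded, peak required to exceed 4× the median
spectral power); the reported f is the median over positions.  Records
shorter than two periods are flagged low-resolution; flat fields are
flagged undefined.

**Wave speed and wavelength.**  At the dominant temporal frequency, the
complex Fourier coefficient of each body position defines a phase profile
along s; for a traveling wave the profile is linear with slope −2π/λ
(λ in body lengths).  The slope is estimated as the median of local phase
increments — robust to the π jumps a standing wave produces at its nodes
(a standing wave therefore reports no propagation and is flagged
incoherent, as is any profile with R² < 0.5 against the fitted line).
c = ±f·λ with the sign encoding the propagation direction along s;
λ·f = |c| holds by construction.  Time-reversing the input flips the sign
of c and leaves f and λ unchanged (asserted in tests).

**Posture envelopes.**  Each skeleton is centered on its centroid and
rotated so its first principal axis (PCA) is horizontal with s = 0 at
negative x; the envelope is the per-position min/max transverse excursion
over one beating period, and the amplitude is the maximum envelope
half-width.  Min/max (rather than a percentile) was chosen because the
synthetic records are short and noise-free; on long noisy records a
percentile envelope would be more robust.

## Synthetic data

The generator is the package's ground-truth instrument.  The worm midline
integrates the tangent angle of the prescribed curvature wave
κ̂(ŝ,t) = A·sin(2π(f·t − ŝ/λ)), ŝ ∈ [0,1], so the curvature field *is* the
generative truth the motility stack must recover; default A = 2.5 rad per
body length, f = 2 Hz, λ = 1 body length, L = 90 px, w = 9 px — a
moderately vigorous undulation far from coiling.  The worm is rasterized
as the exact set of pixels within w/2 of the midline (no anti-aliasing on
masks), and its pixels draw from a two-component intensity mixture; the
centroid can drift at constant speed (the swept path is centered within
the frame).

Four standard fixtures (160×160 px, 40 frames, recorded seeds) emulate the
assay environments: `crawl_like` (uniform bright substrate), `drop_like`
(left-to-right illumination gradient), `microfluidic_like` (hexagonal
pillar lattice, pitch 24 px, radius 5 px, pillar intensities inside the
worm's range so no single threshold separates them), and `noisy` (low
contrast, higher sensor noise).  Sizes were chosen so the full test suite
and the acceptance script each run in about 1–2 minutes.

What the generator does **not** emulate: optical blur (intensity
transitions are sharp at the boundary), appearance drift over a sequence,
shadows, multiple worms, self-occluding coils, and camera motion.  Passing
tests therefore demonstrate the pipeline's correctness under its stated
assumptions (static camera, single worm, stationary appearance), not
robustness to defocus or drift — the appearance models are learned once
and never updated, so slow appearance change will degrade segmentation.

## Degenerate inputs and failure handling

Empty masks raise; a frame whose smoothed segmentation is empty is flagged
failed and skipped by the pipeline (the previous skeleton is carried
forward in the series so the time axis stays aligned).  Coils raise an
unsupported-posture error.  Cells with too few admissible background
samples reduce K with a warning; identical training samples collapse to a
single floored-covariance component.  All outputs of a run (model JSON,
mask PNGs, skeleton/curvature/metric CSVs, run log with config hash and
seeds) are byte-reproducible for a fixed configuration and seed.
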