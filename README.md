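# meme-worm

One-shot appearance-model segmentation and motility analysis for
*Caenorhabditis elegans* image sequences.

Motility assays film a single worm crawling on agar, swimming in a drop or
channel, or threading a microfluidic pillar array ("artificial dirt").
Extracting quantitative behavior from such movies starts with a binary
segmentation of the worm, but intensity thresholding needs per-environment
hand tuning and fails outright when background structures (pillars,
illumination gradients) share the worm's intensity range.  This package
implements a multi-environment model-estimation approach: from **one**
annotated frame — a hand-drawn worm mask plus the worm's width in pixels —
it learns explicit appearance models for both the worm and the background,
then segments every frame of the sequence with a likelihood-ratio test, no
thresholds to tune.

## The model

Vectorized square intensity patches (side ρ, chosen linearly from the worm
width) are modeled with mixtures of Gaussians,

    p(x | M) = Σ_k ω_k · N(x; μ_k, Σ_k),

fitted by expectation-maximization.  One mixture `M_W` is learned from
patches sampled inside the user's worm mask; the image is tiled into
non-overlapping cells c_j and each cell gets its own background mixture
`M_BG,j` (patches centered in the worm mask are excluded; fully occluded
cells inherit their nearest neighbor's model).  A pixel u in cell c_j is
labeled worm when

    p(patch(u) | M_W) / p(patch(u) | M_BG,j)  >  1,

followed by morphological smoothing and a largest-component filter.

From each mask, an ordered midline ("skeleton") is traced on the Euclidean
distance field D: starting at a body end found by a coarse corner detector,
each step moves to the 8-neighbor maximizing likelihood × direction-history
prior, where the likelihood of direction v is proportional to D(x+v) and
the history is a Bayesian direction distribution updated at every step.
Skeleton time series then yield the standard undulation metrics: the
curvature kymograph κ(s, t) (κ = dφ/ds along the body, s = 0 at one end),
body bending frequency f (per-position FFT), wave speed c (phase gradient
of the dominant Fourier component along the body — the slope of the
kymograph's diagonal stripes), wavelength λ = c / f, and PCA-aligned
posture envelopes.

A synthetic movie generator renders worms with traveling-wave curvature
κ(s,t) = A·sin(2π(f·t − s/λ)) on uniform, illumination-gradient,
pillar-array and textured backgrounds, with exact ground-truth masks and
midlines, and a tunable background-subtraction threshold baseline is
included for comparison studies (surface error E_S and worm yield E_Y).

## Worked example

Generate a 60-frame (2 s at 30 fps) synthetic crawling movie whose ground
truth is f = 2 Hz, λ = 1 body length, then run the full pipeline using the
first ground-truth mask as the "user annotation":

```sh
meme synth --preset crawl_like --n-frames 60 --out movie
meme run --frames movie/frames --mask movie/masks/frame_mask_00000.png \
         --width 9 --out analysis --seed 0
cat analysis/metrics.json
```

```json
{
  "amplitude_px": 7.532213690257921,
  "beating_period_s": 0.5,
  "body_length_px": 91.74367149752112,
  "frequency_hz": 2.0,
  "wave_speed_bl_per_s": -1.8638761570730036,
  "wavelength_bl": 0.9319380785365018
}
```

The bending frequency is recovered exactly (2.0 Hz, period 0.5 s); the
wavelength estimate on this short, drifting record is 0.93 body lengths
(it tightens to within ~4% on a 10 s record, see below).  The wave-speed
sign encodes the propagation direction along the skeleton; since no
head/tail identity is assumed, the sign is meaningful only relative to the
skeleton's starting end and flips if tracing starts from the other tip.

Segmentation quality against the generator's ground truth:

```sh
meme eval --pred analysis/masks --truth movie/masks --out report.csv
# E_S = 0.0038 +/- 0.0025, E_Y = 0.9988 +/- 0.0022
```

i.e. 0.4% of pixels misclassified and 99.9% of the worm recovered.
`analysis/` also contains the per-frame masks, the skeleton CSV, the
curvature matrix and a rendered kymograph PNG (red positive / blue negative
curvature).

The same steps are available as library calls (`learn_worm_model`,
`learn_background_model`, `segment_sequence`, `extract_skeleton`,
`compute_metrics`); see the docstrings and `docs/methods.md`.

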