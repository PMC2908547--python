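"""One-shot appearance learning for a worm and its background.

A single annotated frame (grayscale image, binary worm mask, worm width in
pixels) is enough to learn two kinds of appearance models:

* a worm model: one mixture of multivariate Gaussians over vectorized
  square intensity patches sampled inside the user mask, and
* a background model: the image is tiled into non-overlapping rectangular
  cells and each cell gets its own patch mixture, so spatially varying
  illumination and static structures (pillars, vignetting) are modeled
  locally rather than globally.

Patch size scales linearly with the annotated worm width, so a wider worm
is described by larger texture neighborhoods.  All fitting is done with a
seeded expectation-maximization (EM) routine that records its
log-likelihood trajectory, which the tests use to assert EM monotonicity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .errors import ContractViolation, InvalidAnnotationError, LearningError

__all__ = [
    "Frame",
    "UserAnnotation",
    "GaussianComponent",
    "MixtureModel",
    "PatchConfig",
    "BackgroundModel",
    "WormModel",
    "patch_size_from_width",
    "extract_patches",
    "fit_mog",
    "learn_worm_model",
    "learn_background_model",
    "mog_density",
]

# Intensity scale all images are normalized to on load.
INTENSITY_RANGE = 255.0
# Variance floor as a fraction of the squared intensity range.
COV_FLOOR_FRACTION = 1e-4


@dataclass
class Frame:
    """A single grayscale image with intensities in [0, 255]."""

    pixels: NDArray[np.float64]
    t: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ContractViolation("frame must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.pixels)):
            raise ContractViolation("frame intensities must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class UserAnnotation:
    """The one-shot learning input: a frame, a binary worm mask and a width.

    The mask must contain a single connected worm; the width is the body
    width in pixels as marked by the user and drives the patch size.
    """

    frame: Frame
    worm_mask: NDArray[np.bool_]
    worm_width_px: float

    def __post_init__(self) -> None:
        self.worm_mask = np.asarray(self.worm_mask).astype(bool)
        if self.worm_mask.shape != self.frame.shape:
            raise InvalidAnnotationError("mask shape differs from frame shape")
        if self.worm_mask.sum() == 0:
            raise InvalidAnnotationError("worm mask has no foreground pixels")
        if not self.worm_width_px > 0:
            raise InvalidAnnotationError("worm width must be positive")


@dataclass
class GaussianComponent:
    """One weighted multivariate Gaussian of a mixture."""

    weight: float
    mean: NDArray[np.float64]
    covariance: NDArray[np.float64]


@dataclass
class MixtureModel:
    """Mixture of K multivariate Gaussians over vectorized rho x rho patches."""

    weights: NDArray[np.float64]
    means: NDArray[np.float64]        # (K, d)
    covariances: NDArray[np.float64]  # (K, d, d)
    patch_size: int = 1
    log_likelihood_path: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None]
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9):
            raise ContractViolation("mixture weights must sum to 1")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    @property
    def components(self) -> list[GaussianComponent]:
        return [
            GaussianComponent(float(w), m, c)
            for w, m, c in zip(self.weights, self.means, self.covariances)
        ]

    def logpdf(self, samples: NDArray[np.float64]) -> NDArray[np.float64]:
        """Log mixture density for each row of ``samples`` (N, d)."""
        X = np.atleast_2d(np.asarray(samples, dtype=np.float64))
        if X.shape[1] != self.dim:
            raise ContractViolation(
                f"sample dimension {X.shape[1]} != model dimension {self.dim}"
            )
        return logsumexp(
            _component_logpdfs(X, self.means, self.covariances)
            + np.log(self.weights)[None, :],
            axis=1,
        )

    def pdf(self, samples: NDArray[np.float64]) -> NDArray[np.float64]:
        return np.exp(self.logpdf(samples))

    def to_dict(self) -> dict:
        return {
            "patch_size": int(self.patch_size),
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(
            weights=np.array(d["weights"], dtype=np.float64),
            means=np.array(d["means"], dtype=np.float64),
            covariances=np.array(d["covariances"], dtype=np.float64),
            patch_size=int(d["patch_size"]),
        )


@dataclass
class PatchConfig:
    """Patch-extraction and sampling configuration.

    ``slope``/``intercept`` define the linear map from worm width to patch
    size; ``n_samples`` is the number of patches drawn from the worm mask.
    """

    slope: float = 0.25
    intercept: float = 0.5
    n_samples: int = 2000
    seed: int = 0


@dataclass
class WormModel:
    mixture: MixtureModel
    frame_index: int = 0
    mask_area: int = 0
    worm_width_px: float = 0.0

    @property
    def patch_size(self) -> int:
        return self.mixture.patch_size


@dataclass
class BackgroundModel:
    """Grid of per-cell patch mixtures tiling the image.

    ``cell_slices`` holds one ``(row_slice, col_slice)`` per cell; the cells
    are pairwise disjoint and cover every pixel.  ``cell_index`` maps each
    pixel to the cell it belongs to.
    """

    cell_slices: list[tuple[slice, slice]]
    cell_models: list[MixtureModel]
    cell_size: int
    image_shape: tuple[int, int]

    @property
    def n_cells(self) -> int:
        return len(self.cell_models)

    @property
    def patch_size(self) -> int:
        return self.cell_models[0].patch_size

    def cell_index_map(self) -> NDArray[np.intp]:
        idx = np.full(self.image_shape, -1, dtype=np.intp)
        for j, (rs, cs) in enumerate(self.cell_slices):
            idx[rs, cs] = j
        return idx

    def to_dict(self) -> dict:
        return {
            "cell_size": int(self.cell_size),
            "image_shape": list(self.image_shape),
            "cells": [
                {
                    "rows": [s[0].start, s[0].stop],
                    "cols": [s[1].start, s[1].stop],
                    "model": m.to_dict(),
                }
                for s, m in zip(self.cell_slices, self.cell_models)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundModel":
        slices = [
            (slice(c["rows"][0], c["rows"][1]), slice(c["cols"][0], c["cols"][1]))
            for c in d["cells"]
        ]
        models = [MixtureModel.from_dict(c["model"]) for c in d["cells"]]
        return cls(
            cell_slices=slices,
            cell_models=models,
            cell_size=int(d["cell_size"]),
            image_shape=tuple(d["image_shape"]),  # type: ignore[arg-type]
        )


def patch_size_from_width(
    worm_width_px: float,
    config: PatchConfig | None = None,
    image_shape: tuple[int, int] | None = None,
) -> int:
    """Patch side length from the annotated worm width via a linear model.

    rho = round(a * w + b) coerced to the nearest odd integer >= 1 and, when
    the image shape is known, capped at min(H, W) / 4.
    """
    if not worm_width_px > 0:
        raise InvalidAnnotationError("worm width must be positive")
    config = config or PatchConfig()
    rho = int(round(config.slope * worm_width_px + config.intercept))
    if rho < 1:
        rho = 1
    if rho % 2 == 0:
        rho += 1
    if image_shape is not None:
        cap = max(1, int(min(image_shape) / 4))
        if cap % 2 == 0:
            cap -= 1
        rho = min(rho, max(cap, 1))
    return rho


def extract_patches(
    frame: Frame | NDArray[np.float64],
    locations: Sequence[tuple[int, int]] | NDArray[np.intp],
    rho: int,
) -> NDArray[np.float64]:
    """Row-major vectorized rho x rho neighborhoods around pixel locations.

    Locations closer than rho // 2 to the border use edge-replication
    padding so every pixel of the image is admissible.
    """
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame, float)
    if rho < 1 or rho % 2 == 0:
        raise ContractViolation("patch size must be an odd positive integer")
    locs = np.atleast_2d(np.asarray(locations, dtype=np.intp))
    if locs.size == 0:
        raise LearningError("no admissible patch locations")
    half = rho // 2
    padded = np.pad(pixels, half, mode="edge")
    out = np.empty((len(locs), rho * rho), dtype=np.float64)
    for i, (r, c) in enumerate(locs):
        out[i] = padded[r : r + rho, c : c + rho].ravel()
    return out


def _all_patches(pixels: NDArray[np.float64], rho: int) -> NDArray[np.float64]:
    """(H*W, rho^2) matrix of the patch at every pixel, edge-padded."""
    half = rho // 2
    padded = np.pad(pixels, half, mode="edge")
    win = np.lib.stride_tricks.sliding_window_view(padded, (rho, rho))
    return win.reshape(pixels.shape[0] * pixels.shape[1], rho * rho).astype(np.float64)


def _component_logpdfs(
    X: NDArray[np.float64],
    means: NDArray[np.float64],
    covs: NDArray[np.float64],
) -> NDArray[np.float64]:
    """(N, K) matrix of per-component Gaussian log densities."""
    N, d = X.shape
    K = means.shape[0]
    out = np.empty((N, K))
    for k in range(K):
        chol = np.linalg.cholesky(covs[k])
        diff = X - means[k]
        # Solve L z = diff^T; the Mahalanobis distance is ||z||^2.
        sol = solve_triangular(chol, diff.T, lower=True, check_finite=False)
        maha = np.sum(sol**2, axis=0)
        logdet = 2.0 * np.sum(np.log(np.diag(chol)))
        out[:, k] = -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)
    return out


def _cov_floor() -> float:
    return COV_FLOOR_FRACTION * INTENSITY_RANGE**2


def fit_mog(
    samples: NDArray[np.float64],
    n_components: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    cov_floor: float | None = None,
) -> MixtureModel:
    """Fit a Gaussian mixture to sample vectors by expectation-maximization.

    Means are initialized by k-means++ seeding; covariances are floored at
    ``cov_floor`` (default 1e-4 times the squared intensity range) by
    eigenvalue clamping, which keeps every component positive definite even
    on degenerate samples.  Convergence is declared when the relative
    log-likelihood improvement drops below ``tol``.  The fit is
    deterministic for a fixed seed, and the per-iteration log-likelihood is
    stored on the returned model.
    """
    X = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    if X.ndim != 2:
        X = X.reshape(len(X), -1)
    N, d = X.shape
    if cov_floor is None:
        cov_floor = _cov_floor()

    distinct = np.unique(X, axis=0)
    K = int(n_components)
    if K > len(distinct):
        warnings.warn(
            f"requested {K} components but only {len(distinct)} distinct "
            f"samples; falling back to K={len(distinct)}",
            stacklevel=2,
        )
        K = len(distinct)
    if K < 1:
        raise LearningError("need at least one sample to fit a mixture")
    if N < 10 * K * d:
        warnings.warn(
            f"only {N} samples for K={K}, d={d}; fit may be unstable",
            stacklevel=2,
        )

    rng = np.random.default_rng(seed)
    if K == 1:
        means = X.mean(axis=0, keepdims=True)
    elif len(distinct) == K:
        means = distinct.astype(np.float64)
    else:
        means, _ = kmeans_plusplus(
            X, n_clusters=K, random_state=int(rng.integers(2**31 - 1))
        )
        means = means.astype(np.float64)

    # Initial hard assignment to the nearest seed mean.
    d2 = ((X[:, None, :] - means[None]) ** 2).sum(axis=2) if N * K * d < 5e7 else None
    if d2 is None:
        d2 = np.stack([((X - m) ** 2).sum(axis=1) for m in means], axis=1)
    resp = np.zeros((N, K))
    resp[np.arange(N), np.argmin(d2, axis=1)] = 1.0

    weights = np.full(K, 1.0 / K)
    covs = np.empty((K, d, d))
    loglik_path: list[float] = []
    prev_ll = -np.inf
    for it in range(max_iter + 1):
        # M step (the iteration-0 pass turns the hard assignment into params)
        nk = resp.sum(axis=0) + 1e-12
        weights = nk / nk.sum()
        means = (resp.T @ X) / nk[:, None]
        for k in range(K):
            diff = X - means[k]
            cov = (resp[:, k, None] * diff).T @ diff / nk[k]
            covs[k] = _floor_covariance(cov, cov_floor)
        # E step
        log_comp = _component_logpdfs(X, means, covs) + np.log(weights)[None, :]
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        loglik_path.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        if it > 0 and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            break
        prev_ll = ll

    model = MixtureModel(
        weights=weights, means=means, covariances=covs, patch_size=1
    )
    model.log_likelihood_path = loglik_path
    return model


def _floor_covariance(cov: NDArray[np.float64], floor: float) -> NDArray[np.float64]:
    """Clamp eigenvalues of a symmetric matrix at ``floor``."""
    cov = 0.5 * (cov + cov.T)
    vals, vecs = np.linalg.eigh(cov)
    if vals[0] >= floor:
        return cov
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


def mog_density(model: MixtureModel, sample: NDArray[np.float64]) -> float:
    """Mixture density at a single vectorized patch."""
    s = np.asarray(sample, dtype=np.float64).ravel()
    if s.size != model.dim:
        raise ContractViolation(
            f"sample length {s.size} != model dimension {model.dim}"
        )
    return float(model.pdf(s[None])[0])


def learn_worm_model(
    annotation: UserAnnotation,
    n_components: int = 3,
    config: PatchConfig | None = None,
) -> WormModel:
    """Learn the worm appearance mixture from the annotated frame.

    ``n_samples`` patch locations are drawn uniformly at random from inside
    the worm mask (with replacement whenever the mask is smaller than the
    requested sample count) and their vectorized patches are fitted by EM.
    """
    config = config or PatchConfig()
    rho = patch_size_from_width(
        annotation.worm_width_px, config, annotation.frame.shape
    )
    rows, cols = np.nonzero(annotation.worm_mask)
    if len(rows) == 0:
        raise InvalidAnnotationError("worm mask has no foreground pixels")
    rng = np.random.default_rng(config.seed)
    replace = len(rows) < config.n_samples
    pick = rng.choice(len(rows), size=config.n_samples, replace=replace)
    locs = np.stack([rows[pick], cols[pick]], axis=1)
    patches = extract_patches(annotation.frame, locs, rho)
    mixture = fit_mog(patches, n_components, seed=config.seed)
    mixture.patch_size = rho
    return WormModel(
        mixture=mixture,
        frame_index=annotation.frame.t,
        mask_area=int(annotation.worm_mask.sum()),
        worm_width_px=float(annotation.worm_width_px),
    )


def _tile_image(shape: tuple[int, int], cell_size: int) -> list[tuple[slice, slice]]:
    """Disjoint rectangular cells covering the image; edge cells may be smaller."""
    H, W = shape
    slices = []
    for r0 in range(0, H, cell_size):
        for c0 in range(0, W, cell_size):
            slices.append(
                (slice(r0, min(r0 + cell_size, H)), slice(c0, min(c0 + cell_size, W)))
            )
    return slices


def learn_background_model(
    annotation: UserAnnotation,
    n_components: int = 3,
    cell_size: int = 32,
    config: PatchConfig | None = None,
) -> BackgroundModel:
    """Learn one patch mixture per background grid cell.

    Patches whose center pixel lies inside the user's worm mask are excluded
    from training, so the worm never contaminates the background model.  A
    cell entirely covered by the worm inherits the model of the nearest cell
    that had admissible samples, mirroring the idea that occluded background
    can be described by its neighborhood.
    """
    config = config or PatchConfig()
    rho = patch_size_from_width(
        annotation.worm_width_px, config, annotation.frame.shape
    )
    if cell_size < rho:
        raise ContractViolation("cell size must be at least the patch size")
    pixels = annotation.frame.pixels
    slices = _tile_image(annotation.frame.shape, cell_size)
    patches = _all_patches(pixels, rho)
    W = pixels.shape[1]
    mask = annotation.worm_mask

    models: list[MixtureModel | None] = []
    centers = []
    for rs, cs in slices:
        rr, cc = np.mgrid[rs, cs]
        admissible = ~mask[rr, cc]
        centers.append(((rs.start + rs.stop) / 2.0, (cs.start + cs.stop) / 2.0))
        flat = (rr[admissible] * W + cc[admissible]).ravel()
        if flat.size == 0:
            models.append(None)
            continue
        cell_samples = patches[flat]
        k = n_components
        if len(np.unique(cell_samples, axis=0)) < max(k, 2) or flat.size < k * rho**2:
            k = max(1, min(k, len(np.unique(cell_samples, axis=0))))
            if k < n_components:
                warnings.warn(
                    "background cell has too few admissible samples; "
                    f"reducing K to {k}",
                    stacklevel=2,
                )
        m = fit_mog(cell_samples, k, seed=config.seed)
        m.patch_size = rho
        models.append(m)

    # Fully occluded cells inherit the nearest fitted neighbor's model.
    fitted = [j for j, m in enumerate(models) if m is not None]
    if not fitted:
        raise LearningError("worm mask covers the entire image; no background left")
    centers_arr = np.asarray(centers)
    for j, m in enumerate(models):
        if m is None:
            d2 = ((centers_arr[fitted] - centers_arr[j]) ** 2).sum(axis=1)
            models[j] = models[fitted[int(np.argmin(d2))]]

    return BackgroundModel(
        cell_slices=slices,
        cell_models=[m for m in models if m is not None],
        cell_size=cell_size,
        image_shape=annotation.frame.shape,
    )
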