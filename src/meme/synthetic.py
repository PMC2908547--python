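"""Synthetic worm movies with exact ground truth.

The generator renders a single undulating worm as a constant-width tube
around a parametric midline whose curvature is the traveling wave

    kappa_hat(s_hat, t) = A * sin(2*pi*(f*t - s_hat/lambda) + phase)

with s_hat in [0, 1] the normalized arc length (head at 0), A the
dimensionless curvature amplitude (radians per unit body length), f the
undulation frequency in Hz and lambda the wavelength in body lengths.  The
midline is built by integrating the tangent angle, so the curvature field
is the generative ground truth that the motility pipeline must recover.

Backgrounds emulate the common assay environments: a homogeneous bright
substrate (crawling plates), a horizontal illumination gradient (drops,
vignetting), a static pillar array whose intensities overlap the worm's
(microfluidic "artificial dirt", the regime where a single threshold
cannot separate worm from background), and a two-tone texture.  Pixel
intensities are drawn from per-region Gaussian mixtures plus sensor noise;
masks are exact rasterizations of the worm tube (no anti-aliasing).

Everything is deterministic given the scene seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator

import numpy as np
from numpy.typing import NDArray
from scipy.integrate import cumulative_trapezoid
from scipy.spatial import cKDTree

from .appearance import Frame, UserAnnotation
from .errors import ContractViolation

__all__ = [
    "WormSpec",
    "SceneSpec",
    "GroundTruthBundle",
    "render_worm_frame",
    "generate_sequence",
    "standard_fixture_suite",
    "STANDARD_FIXTURES",
]


@dataclass
class WormSpec:
    """Geometry, kinematics and appearance of the synthetic worm."""

    length_px: float = 90.0
    width_px: float = 9.0
    curvature_amplitude: float = 2.5   # rad per unit body length
    frequency_hz: float = 2.0
    wavelength_bl: float = 1.0
    phase: float = 0.0
    heading_rad: float = 0.3
    speed_px_per_frame: float = 0.0
    trajectory_offset_px: tuple[float, float] = (0.0, 0.0)
    # Worm intensity mixture (two-tone body by default: dark muscle + gut).
    intensity_means: tuple[float, ...] = (55.0, 85.0)
    intensity_sds: tuple[float, ...] = (7.0, 7.0)
    intensity_weights: tuple[float, ...] = (0.65, 0.35)

    def __post_init__(self) -> None:
        if not self.length_px > self.width_px > 0:
            raise ContractViolation("need length > width > 0")
        if self.curvature_amplitude < 0:
            raise ContractViolation("curvature amplitude must be >= 0")
        w = np.asarray(self.intensity_weights, float)
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ContractViolation("worm intensity weights must form a mixture")


@dataclass
class SceneSpec:
    """Background type, geometry and acquisition parameters of the movie."""

    background: str = "uniform"  # uniform | gradient | pillars | textured
    shape: tuple[int, int] = (160, 160)
    fps: float = 30.0
    noise_sd: float = 3.0
    seed: int = 0
    # Background intensity parameters (interpreted per background type).
    bg_mean: float = 200.0
    bg_sd: float = 8.0
    gradient_range: tuple[float, float] = (120.0, 230.0)
    pillar_mean: float = 70.0
    pillar_sd: float = 9.0
    pillar_radius_px: float = 5.0
    pillar_pitch_px: float = 24.0
    texture_means: tuple[float, float] = (150.0, 215.0)

    def __post_init__(self) -> None:
        if self.background not in ("uniform", "gradient", "pillars", "textured"):
            raise ContractViolation(f"unknown background type {self.background!r}")


@dataclass
class GroundTruthBundle:
    """Frames with exact per-frame masks and sub-pixel midlines."""

    frames: list[Frame]
    masks: list[NDArray[np.bool_]]
    midlines: list[NDArray[np.float64]]  # (n, 2) sub-pixel (row, col), head first
    worm: WormSpec
    scene: SceneSpec
    name: str = ""

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def annotation(self, frame_index: int = 0) -> UserAnnotation:
        """Emulated user input: the true mask and width of one frame."""
        return UserAnnotation(
            frame=self.frames[frame_index],
            worm_mask=self.masks[frame_index],
            worm_width_px=self.worm.width_px,
        )

    def true_curvature(
        self, s_hat: NDArray[np.float64], t_index: int
    ) -> NDArray[np.float64]:
        """Analytic midline curvature in 1/px at normalized positions."""
        t = t_index / self.scene.fps
        w = self.worm
        kappa_hat = w.curvature_amplitude * np.sin(
            2.0 * np.pi * (w.frequency_hz * t - s_hat / w.wavelength_bl) + w.phase
        )
        return kappa_hat / w.length_px

    def iter_frames(self) -> Iterator[tuple[Frame, NDArray[np.bool_]]]:
        yield from zip(self.frames, self.masks)


def _midline_points(
    worm: WormSpec, scene: SceneSpec, t_index: int, n_samples: int = 400
) -> NDArray[np.float64]:
    """Sub-pixel midline (row, col) by integrating the tangent angle."""
    t = t_index / scene.fps
    s_hat = np.linspace(0.0, 1.0, n_samples)
    kappa_hat = worm.curvature_amplitude * np.sin(
        2.0 * np.pi * (worm.frequency_hz * t - s_hat / worm.wavelength_bl)
        + worm.phase
    )
    phi = worm.heading_rad + cumulative_trapezoid(kappa_hat, s_hat, initial=0.0)
    x = worm.length_px * cumulative_trapezoid(np.cos(phi), s_hat, initial=0.0)
    y = worm.length_px * cumulative_trapezoid(np.sin(phi), s_hat, initial=0.0)
    pts = np.stack([y, x], axis=1)  # (row, col)
    # Re-anchor: centroid follows the prescribed trajectory.
    H, W = scene.shape
    center = np.array([H / 2.0, W / 2.0])
    drift_dir = np.array([np.sin(worm.heading_rad), np.cos(worm.heading_rad)])
    offset = t_index * worm.speed_px_per_frame * drift_dir
    pts = pts - pts.mean(axis=0) + center + offset + np.asarray(
        worm.trajectory_offset_px
    )
    return pts


def _background_image(scene: SceneSpec, rng: np.random.Generator) -> NDArray[np.float64]:
    """Static background pattern (no sensor noise); fixed by the scene seed."""
    H, W = scene.shape
    if scene.background == "uniform":
        return rng.normal(scene.bg_mean, scene.bg_sd, size=(H, W))
    if scene.background == "gradient":
        lo, hi = scene.gradient_range
        ramp = np.linspace(lo, hi, W)[None, :].repeat(H, axis=0)
        return ramp + rng.normal(0.0, scene.bg_sd * 0.75, size=(H, W))
    if scene.background == "pillars":
        img = rng.normal(scene.bg_mean, scene.bg_sd, size=(H, W))
        rr, cc = np.mgrid[:H, :W]
        pitch = scene.pillar_pitch_px
        for i, r0 in enumerate(np.arange(pitch / 2, H, pitch)):
            row_offset = (pitch / 2) * (i % 2)
            for c0 in np.arange(pitch / 2 + row_offset, W, pitch):
                disk = (rr - r0) ** 2 + (cc - c0) ** 2 <= scene.pillar_radius_px**2
                img[disk] = rng.normal(
                    scene.pillar_mean, scene.pillar_sd, size=int(disk.sum())
                )
        return img
    # textured: static two-tone pattern
    lo, hi = scene.texture_means
    blocks = rng.random((H, W)) < 0.5
    img = np.where(blocks, lo, hi) + rng.normal(0.0, scene.bg_sd, size=(H, W))
    return img


def _worm_intensities(
    worm: WormSpec, n: int, rng: np.random.Generator
) -> NDArray[np.float64]:
    comp = rng.choice(
        len(worm.intensity_means), size=n, p=np.asarray(worm.intensity_weights)
    )
    means = np.asarray(worm.intensity_means)[comp]
    sds = np.asarray(worm.intensity_sds)[comp]
    return rng.normal(means, sds)


def render_worm_frame(
    worm: WormSpec, scene: SceneSpec, t_index: int
) -> tuple[Frame, NDArray[np.bool_], NDArray[np.float64]]:
    """Render one frame: image, exact mask and sub-pixel midline.

    Deterministic given the scene seed and frame index; the static
    background pattern depends only on the seed, while worm texture and
    sensor noise are redrawn per frame.
    """
    H, W = scene.shape
    midline = _midline_points(worm, scene, t_index)
    half = worm.width_px / 2.0
    if (
        midline[:, 0].min() < half + 1
        or midline[:, 1].min() < half + 1
        or midline[:, 0].max() > H - half - 2
        or midline[:, 1].max() > W - half - 2
    ):
        raise ContractViolation(f"worm leaves the frame at t={t_index}")

    # Exact rasterization: pixels whose center is within width/2 of the
    # midline polyline (sampled densely enough that the polyline-vs-curve
    # gap is far below half a pixel).
    tree = cKDTree(midline)
    rr, cc = np.mgrid[:H, :W]
    centers = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dist, _ = tree.query(centers, k=1)
    mask = (dist.reshape(H, W) <= half)

    bg_rng = np.random.default_rng([scene.seed, 0])
    background = _background_image(scene, bg_rng)
    frame_rng = np.random.default_rng([scene.seed, 1, t_index])
    img = background + frame_rng.normal(0.0, scene.noise_sd, size=(H, W))
    n_worm = int(mask.sum())
    img[mask] = _worm_intensities(worm, n_worm, frame_rng) + frame_rng.normal(
        0.0, scene.noise_sd, size=n_worm
    )
    img = np.clip(img, 0.0, 255.0)

    keep = np.linspace(0, len(midline) - 1, 101).astype(int)
    return Frame(pixels=img, t=t_index), mask, midline[keep]


def generate_sequence(
    worm: WormSpec, scene: SceneSpec, n_frames: int
) -> GroundTruthBundle:
    """Render a full movie with aligned per-frame ground truth."""
    if n_frames < 1:
        raise ContractViolation("need at least one frame")
    if worm.speed_px_per_frame != 0.0 and worm.trajectory_offset_px == (0.0, 0.0):
        # Center the swept path so a drifting worm stays in frame.
        drift_dir = np.array([np.sin(worm.heading_rad), np.cos(worm.heading_rad)])
        shift = -0.5 * (n_frames - 1) * worm.speed_px_per_frame * drift_dir
        worm = replace(worm, trajectory_offset_px=(float(shift[0]), float(shift[1])))
    frames, masks, midlines = [], [], []
    for t in range(n_frames):
        frame, mask, midline = render_worm_frame(worm, scene, t)
        frames.append(frame)
        masks.append(mask)
        midlines.append(midline)
    return GroundTruthBundle(
        frames=frames, masks=masks, midlines=midlines, worm=worm, scene=scene
    )


# Named fixture definitions: (worm spec, scene spec, n_frames).  The seeds
# are part of the definition so every fixture regenerates identically.
STANDARD_FIXTURES: dict[str, tuple[WormSpec, SceneSpec, int]] = {
    "crawl_like": (
        WormSpec(speed_px_per_frame=0.6),
        SceneSpec(background="uniform", seed=101),
        40,
    ),
    "drop_like": (
        WormSpec(speed_px_per_frame=0.6),
        SceneSpec(background="gradient", seed=202),
        40,
    ),
    "microfluidic_like": (
        WormSpec(speed_px_per_frame=0.6),
        SceneSpec(background="pillars", seed=303),
        40,
    ),
    "noisy": (
        WormSpec(
            speed_px_per_frame=0.6,
            intensity_means=(110.0, 135.0),
            intensity_sds=(9.0, 9.0),
        ),
        SceneSpec(background="uniform", bg_mean=175.0, bg_sd=10.0, noise_sd=6.0,
                  seed=404),
        40,
    ),
}


def standard_fixture_suite(
    n_frames: int | None = None,
) -> dict[str, GroundTruthBundle]:
    """The four named test environments, regenerated from recorded seeds.

    ``n_frames`` overrides the per-fixture frame count (useful for quick
    smoke runs); the default counts keep each movie a few undulation
    periods long.
    """
    suite = {}
    for name, (worm, scene, T) in STANDARD_FIXTURES.items():
        bundle = generate_sequence(worm, scene, n_frames or T)
        bundle.name = name
        suite[name] = bundle
    return suite


def drifting_worm(speed_px_per_frame: float, **kwargs) -> WormSpec:
    """Convenience: a default worm with a prescribed centroid speed."""
    return replace(WormSpec(), speed_px_per_frame=speed_px_per_frame, **kwargs)
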