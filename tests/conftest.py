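"""Shared fixtures: small synthetic bundles and learned models.

Everything is generated programmatically from recorded seeds; nothing is
read from disk.  Session scope keeps the expensive renders and model fits
shared across test modules.
"""

import warnings

import numpy as np
import pytest

from meme.appearance import learn_background_model, learn_worm_model
from meme.synthetic import (
    STANDARD_FIXTURES,
    SceneSpec,
    WormSpec,
    generate_sequence,
)


@pytest.fixture(scope="session")
def crawl_bundle():
    """A short uniform-background movie with ground truth."""
    worm, scene, _ = STANDARD_FIXTURES["crawl_like"]
    return generate_sequence(worm, scene, 10)


@pytest.fixture(scope="session")
def pillar_bundle():
    worm, scene, _ = STANDARD_FIXTURES["microfluidic_like"]
    return generate_sequence(worm, scene, 10)


@pytest.fixture(scope="session")
def gradient_bundle():
    worm, scene, _ = STANDARD_FIXTURES["drop_like"]
    return generate_sequence(worm, scene, 10)


@pytest.fixture(scope="session")
def crawl_models(crawl_bundle):
    """Worm and background models learned from the crawl bundle's frame 0."""
    ann = crawl_bundle.annotation(0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        worm = learn_worm_model(ann, 3)
        bg = learn_background_model(ann, 3, 32)
    return worm, bg


@pytest.fixture(scope="session")
def wave_bundle():
    """A longer stationary-worm movie for motility recovery tests."""
    worm = WormSpec(frequency_hz=2.0, wavelength_bl=1.0, curvature_amplitude=2.5)
    scene = SceneSpec(seed=11, fps=30.0)
    return generate_sequence(worm, scene, 120)


def random_worm_mask(rng: np.random.Generator):
    """One rendered worm mask with randomized posture, for tracer fuzzing."""
    worm = WormSpec(
        curvature_amplitude=float(rng.uniform(0.0, 3.5)),
        phase=float(rng.uniform(0, 2 * np.pi)),
        heading_rad=float(rng.uniform(0, 2 * np.pi)),
        length_px=float(rng.uniform(60, 100)),
        width_px=float(rng.uniform(6, 11)),
    )
    scene = SceneSpec(seed=int(rng.integers(2**31 - 1)))
    from meme.synthetic import _midline_points
    from scipy.spatial import cKDTree

    mid = _midline_points(worm, scene, 0)
    H, W = scene.shape
    tree = cKDTree(mid)
    rr, cc = np.mgrid[:H, :W]
    d, _ = tree.query(np.stack([rr.ravel(), cc.ravel()], 1).astype(float))
    return (d.reshape(H, W) <= worm.width_px / 2.0), worm
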