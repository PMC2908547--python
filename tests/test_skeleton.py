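"""Unit and property tests for the distance field and the midline tracer."""

import numpy as np
import pytest

from meme.errors import SkeletonizationError, UnsupportedPostureError
from meme.skeleton import (
    DIRECTIONS,
    TracerConfig,
    direction_likelihood,
    distance_field,
    extract_skeleton,
    find_endpoint,
    find_endpoints,
    map_step,
    resample_skeleton,
    skeleton_arc_length,
    smooth_path,
    update_direction_distribution,
)

from conftest import random_worm_mask


def brute_force_distance(mask):
    """All-pairs Euclidean distance to the nearest background pixel."""
    mask = np.asarray(mask, bool)
    H, W = mask.shape
    bg = np.argwhere(~mask)
    out = np.zeros((H, W))
    for r, c in np.argwhere(mask):
        d2 = (bg[:, 0] - r) ** 2 + (bg[:, 1] - c) ** 2
        out[r, c] = np.sqrt(d2.min()) if len(bg) else np.inf
    return out


def test_distance_field_matches_bruteforce_on_random_masks():
    rng = np.random.default_rng(0)
    for _ in range(60):
        h, w = rng.integers(3, 21, 2)
        mask = rng.random((h, w)) < rng.uniform(0.2, 0.8)
        if not mask.any() or mask.all():
            continue
        assert np.array_equal(distance_field(mask), brute_force_distance(mask))


def test_distance_field_simple_shapes():
    single = np.zeros((5, 5), bool)
    single[2, 2] = True
    assert distance_field(single)[2, 2] == 1.0
    # rasterized disk: maximum distance within 1 px of the radius
    rr, cc = np.mgrid[:41, :41]
    disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 15**2
    D = distance_field(disk)
    assert abs(D.max() - 15) <= 1.0
    with pytest.raises(SkeletonizationError):
        distance_field(np.zeros((4, 4), bool))


def test_find_endpoint_on_bar_returns_an_end():
    mask = np.zeros((9, 27), bool)
    mask[3:6, 3:24] = True
    p1, p2 = find_endpoints(mask, 3.0)
    ends = {(4, 3), (4, 23), (3, 3), (5, 3), (3, 23), (5, 23)}
    assert p1 in ends and p2 in ends
    assert abs(p1[1] - p2[1]) > 10  # opposite ends
    assert find_endpoint(mask, 3.0) == p1


def test_find_endpoint_near_true_tip_on_curved_worm():
    rng = np.random.default_rng(7)
    mask, worm = random_worm_mask(rng)

    p = find_endpoint(mask, worm.width_px)
    # endpoint should be close to one of the tube tips; the tube extends
    # width/2 beyond the midline ends
    from scipy.spatial import cKDTree

    sk = extract_skeleton(mask, worm.width_px)
    tips = np.array([sk.points[0], sk.points[-1]])
    assert np.min(np.hypot(*(tips - np.array(p)).T)) <= 3.0


def test_find_endpoint_warns_on_disk():
    rr, cc = np.mgrid[:31, :31]
    disk = (rr - 15) ** 2 + (cc - 15) ** 2 <= 121
    with pytest.warns(UserWarning, match="diffuse"):
        p = find_endpoint(disk, 11.0)
    assert disk[p]


def test_direction_likelihood_proportional_and_uniform_cases():
    D = np.zeros((5, 5))
    D[1:4, 1:4] = 1.0
    D[2, 3] = 3.0
    lik = direction_likelihood(D, (2, 2))
    assert lik.sum() == pytest.approx(1.0)
    east = np.argmax([np.array_equal(v, (0, 1)) for v in DIRECTIONS])
    assert np.argmax(lik) == east
    # all equal neighbors -> uniform 1/8
    Du = np.ones((5, 5))
    lik_u = direction_likelihood(Du, (2, 2))
    assert np.allclose(lik_u, 1.0 / 8.0)
    # hand-built arithmetic oracle
    Dh = np.arange(25, dtype=float).reshape(5, 5)
    lik_h = direction_likelihood(Dh, (2, 2))
    vals = np.array([Dh[2 + v[0], 2 + v[1]] for v in DIRECTIONS], float)
    assert np.allclose(lik_h, vals / vals.sum())


def test_map_step_matches_bruteforce_argmax_on_random_fields():
    rng = np.random.default_rng(1)
    for _ in range(100):
        D = rng.random((7, 7))
        P = rng.random(8)
        P /= P.sum()
        got = map_step((3, 3), P, D)
        assert got is not None
        nxt, choice, lik = got
        prods = lik * P
        assert prods[choice] == pytest.approx(prods.max())
        assert nxt == (3 + DIRECTIONS[choice][0], 3 + DIRECTIONS[choice][1])


def test_map_step_history_dominates_on_ties():
    D = np.ones((5, 5))
    P = np.full(8, 1e-6)
    east = [i for i, v in enumerate(DIRECTIONS) if tuple(v) == (0, 1)][0]
    P[east] = 1.0 - 7e-6
    nxt, choice, _ = map_step((2, 2), P, D)
    assert choice == east and nxt == (2, 3)


def test_bayes_update_flat_prior_and_flat_likelihood():
    uniform = np.full(8, 1.0 / 8.0)
    lik = np.array([1, 2, 3, 4, 4, 3, 2, 1], float)
    lik /= lik.sum()
    post = update_direction_distribution(uniform, lik)
    assert np.allclose(post, lik)
    post2 = update_direction_distribution(lik, uniform)
    assert np.allclose(post2, lik)
    # two sequential hand updates
    p = update_direction_distribution(uniform, lik)
    p = update_direction_distribution(p, lik)
    hand = lik * lik
    assert np.allclose(p, hand / hand.sum())
    assert update_direction_distribution(uniform, np.zeros(8)) is None


def test_extract_skeleton_on_horizontal_bar():
    mask = np.zeros((9, 27), bool)
    mask[3:6, 3:24] = True
    sk = extract_skeleton(mask, 3.0)
    assert 19 <= len(sk) <= 23
    # max perpendicular deviation from the middle row is at most 1 px
    assert np.max(np.abs(sk.points[:, 0] - 4)) <= 1
    assert sk.points[:, 1].min() <= 4 and sk.points[:, 1].max() >= 22


@pytest.mark.parametrize("amplitude", [0.0, 1.0, 2.5, 4.0])
def test_skeleton_tracks_true_midline_across_amplitudes(amplitude):
    from scipy.spatial import cKDTree

    from meme.synthetic import SceneSpec, WormSpec, generate_sequence

    worm = WormSpec(curvature_amplitude=amplitude)
    bundle = generate_sequence(worm, SceneSpec(seed=21), 2)
    for t in range(2):
        sk = extract_skeleton(bundle.masks[t], worm.width_px, t=t)
        tree = cKDTree(bundle.midlines[t])
        d, _ = tree.query(sk.points.astype(float))
        assert np.sqrt(np.mean(d**2)) <= 1.5
        arc = skeleton_arc_length(smooth_path(sk.points))
        true_arc = skeleton_arc_length(bundle.midlines[t])
        assert arc >= 0.9 * true_arc
        # all skeleton points strictly inside the mask
        assert bundle.masks[t][sk.points[:, 0], sk.points[:, 1]].all()


def test_skeleton_robust_to_boundary_noise():
    from scipy.spatial import cKDTree

    from meme.synthetic import SceneSpec, WormSpec, generate_sequence
    from skimage import morphology

    worm = WormSpec(curvature_amplitude=2.0)
    bundle = generate_sequence(worm, SceneSpec(seed=31), 1)
    mask = bundle.masks[0]
    rng = np.random.default_rng(5)
    # speckle the boundary: flip a third of the boundary ring
    boundary = mask & ~morphology.erosion(mask, morphology.disk(1))
    noisy = mask.copy()
    flip = boundary & (rng.random(mask.shape) < 0.33)
    noisy[flip] = False
    clean_sk = extract_skeleton(mask, worm.width_px)
    noisy_sk = extract_skeleton(noisy, worm.width_px)
    tree = cKDTree(clean_sk.points.astype(float))
    d, _ = tree.query(noisy_sk.points.astype(float))
    assert np.mean(d) <= 1.0


def test_tracer_contracts_on_random_masks():
    """Direction distributions stay normalized; no revisits; bounded steps."""
    rng = np.random.default_rng(17)
    for _ in range(40):
        mask, worm = random_worm_mask(rng)
        cfg = TracerConfig()
        sk = extract_skeleton(mask, worm.width_px, config=cfg)
        P_hist = np.array(cfg.history_probabilities)
        assert np.all(P_hist >= 0)
        assert np.allclose(P_hist.sum(axis=1), 1.0, atol=1e-12)
        pts = [tuple(p) for p in sk.points]
        assert len(pts) == len(set(pts))  # no revisit
        assert len(pts) <= mask.sum()


def test_coiled_mask_raises_unsupported_posture():
    rr, cc = np.mgrid[:31, :31]
    annulus = ((rr - 15) ** 2 + (cc - 15) ** 2 <= 144) & (
        (rr - 15) ** 2 + (cc - 15) ** 2 >= 36
    )
    with pytest.raises(UnsupportedPostureError):
        extract_skeleton(annulus)


def test_resample_skeleton_uniform_spacing():
    line = np.stack([np.zeros(10), np.arange(10.0)], axis=1)
    r = resample_skeleton(line, 5)
    assert np.allclose(r[:, 1], [0, 2.25, 4.5, 6.75, 9.0])
    # semicircle: equal chords
    th = np.linspace(0, np.pi, 400)
    semi = np.stack([10 * np.sin(th), 10 * np.cos(th)], axis=1)
    chords = np.hypot(*np.diff(resample_skeleton(semi, 11), axis=0).T)
    assert chords.max() - chords.min() < 1e-3
    # n = 2 gives the endpoints
    two = resample_skeleton(line, 2)
    assert np.array_equal(two, line[[0, -1]])
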