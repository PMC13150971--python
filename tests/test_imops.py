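"""Primitives: stretching, local statistics, CLAHE, reconstruction, morphology."""

import numpy as np
import pytest
from scipy import ndimage
from skimage import morphology as skmorph

from lungprior import imops

from conftest import rng_images


# ---------------------------------------------------------------------------
# contrast stretch
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("data,lo,hi,expected", [
    ([0.0, 0.5, 1.0], 0.0, 1.0, [0.0, 0.5, 1.0]),
    ([0.05, 0.5, 0.95], 0.05, 0.95, [0.0, 0.5, 1.0]),
])
def test_contrast_stretch_maps_bounds(data, lo, hi, expected):
    img = np.array([data, data])
    out = imops.contrast_stretch(img, lo, hi)
    np.testing.assert_allclose(out[0], expected, atol=1e-12)


def test_contrast_stretch_clamps_below_lo():
    out = imops.contrast_stretch(np.full((8, 8), 0.3), 0.4, 1.0)
    assert np.all(out == 0.0)


def test_contrast_stretch_monotone_and_rejects_bad_bounds():
    img = rng_images(1, seed=3)[0]
    out = imops.contrast_stretch(img, 0.2, 0.8)
    order = np.argsort(img.ravel())
    assert np.all(np.diff(out.ravel()[order]) >= -1e-12)
    with pytest.raises(ValueError):
        imops.contrast_stretch(img, 0.5, 0.5)


# ---------------------------------------------------------------------------
# local std epsilon
# ---------------------------------------------------------------------------

def epsilon_bruteforce(img, window):
    """Independent oracle: explicit double loop over clipped windows."""
    arr = np.asarray(img, dtype=np.float64)
    M, N = arr.shape
    m, n = window
    if arr.max() == 0 or arr.max() == arr.min():
        return 0.0
    stds = np.empty((M, N))
    for x in range(M):
        for y in range(N):
            r0, r1 = max(0, x - (m - 1) // 2), min(M, x + m // 2 + 1)
            c0, c1 = max(0, y - (n - 1) // 2), min(N, y + n // 2 + 1)
            stds[x, y] = np.std(arr[r0:r1, c0:c1])
    return float(stds.mean() / arr.max())


def test_epsilon_constant_is_zero():
    stats = imops.local_std_epsilon(np.full((12, 10), 0.4))
    assert stats.epsilon == 0.0


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_epsilon_matches_exhaustive_oracle(seed):
    img = rng_images(1, shape=(16, 13), seed=seed)[0]
    stats = imops.local_std_epsilon(img)
    oracle = epsilon_bruteforce(img, (stats.window_rows, stats.window_cols))
    assert abs(stats.epsilon - oracle) < 1e-12


def test_epsilon_checkerboard_matches_oracle():
    img = np.indices((4, 4)).sum(axis=0) % 2 * 1.0
    stats = imops.local_std_epsilon(img)
    oracle = epsilon_bruteforce(img, (stats.window_rows, stats.window_cols))
    assert abs(stats.epsilon - oracle) < 1e-12
    assert stats.epsilon > 0


def test_epsilon_scale_invariance():
    img = rng_images(1, seed=9)[0]
    e1 = imops.local_std_epsilon(img).epsilon
    e2 = imops.local_std_epsilon(0.5 * img).epsilon
    assert abs(e1 - e2) < 1e-12


# ---------------------------------------------------------------------------
# histogram valley
# ---------------------------------------------------------------------------

def _image_from_levels(levels):
    arr = np.asarray(levels, dtype=np.float64) / 255.0
    return arr.reshape(1, -1)


def test_valley_between_engineered_modes():
    # two plateaus flanking the search range and a V-shaped floor whose
    # unique minimum sits at bin 150
    levels = []
    levels.extend(np.arange(110, 130).repeat(200))   # dark mode
    levels.extend(np.arange(171, 191).repeat(200))   # bright mode
    for b in range(130, 171):
        levels.extend([b] * (50 + 5 * abs(b - 150)))
    img = _image_from_levels(levels)
    t = imops.histogram_valley_threshold(img, (130, 170))
    assert abs(t * 255 - 150) <= 1


def test_valley_constant_image_falls_back_to_midpoint():
    t = imops.histogram_valley_threshold(np.full((6, 6), 0.5), (130, 170))
    assert t == pytest.approx(150 / 255)


def test_valley_tie_breaks_to_lowest_bin():
    # equal minima engineered at bins 140 and 160 (5-bin plateaus so the
    # moving average preserves the tie), everything else higher
    levels = []
    for b in range(130, 171):
        count = 2 if b in range(138, 143) or b in range(158, 163) else 10
        levels.extend([b] * count)
    img = _image_from_levels(levels * 30)
    t = imops.histogram_valley_threshold(img, (130, 170))
    assert t == pytest.approx(140 / 255)


def test_valley_rejects_bad_range():
    with pytest.raises(ValueError):
        imops.histogram_valley_threshold(np.zeros((4, 4)), (170, 130))


# ---------------------------------------------------------------------------
# CLAHE
# ---------------------------------------------------------------------------

def test_clahe_constant_image_unchanged():
    img = np.full((32, 32), 0.7)
    for dist, alpha in [("uniform", None), ("rayleigh", 0.4)]:
        out = imops.clahe_enhance(img, (4, 4), 0.01, dist, 256, alpha)
        np.testing.assert_array_equal(out, img)


def test_clahe_single_tile_uniform_ramp_is_near_identity():
    # global equalization of a uniform ramp is (approximately) the identity
    ramp = np.tile(np.linspace(0, 1, 256), (64, 1))
    out = imops.clahe_enhance(ramp, (1, 1), 1.0, "uniform", 256)
    assert np.abs(out - ramp).max() < 0.02


def test_clahe_output_in_unit_interval():
    for i, img in enumerate(rng_images(10, shape=(40, 40), seed=5)):
        out = imops.clahe_enhance(img, (5, 5), 0.01, "rayleigh", 128, 0.5)
        assert out.min() >= 0.0 and out.max() <= 1.0


def test_clahe_requires_alpha_for_rayleigh():
    with pytest.raises(ValueError):
        imops.clahe_enhance(np.zeros((8, 8)), (2, 2), 0.01, "rayleigh", 64)


# ---------------------------------------------------------------------------
# reconstruction
# ---------------------------------------------------------------------------

def reconstruct_oracle(mask, seed):
    """Independent route: grayscale morphological reconstruction by dilation."""
    marker = (mask & seed).astype(float)
    rec = skmorph.reconstruction(marker, mask.astype(float),
                                 footprint=np.ones((3, 3)))
    return rec > 0.5


def test_reconstruct_matches_oracle_on_random_pairs():
    rng = np.random.default_rng(42)
    for _ in range(100):
        mask = ndimage.binary_dilation(rng.random((32, 32)) > 0.8)
        seed = rng.random((32, 32)) > 0.9
        ours = imops.reconstruct_components(mask, seed)
        np.testing.assert_array_equal(ours, reconstruct_oracle(mask, seed))


def test_reconstruct_component_selection():
    mask = np.zeros((20, 20), bool)
    mask[2:6, 2:6] = True      # component A
    mask[12:16, 12:16] = True  # component B
    seed = np.zeros_like(mask)
    seed[3, 3] = True
    out = imops.reconstruct_components(mask, seed)
    assert out[2:6, 2:6].all() and not out[12:16, 12:16].any()


def test_reconstruct_edge_cases_and_idempotence():
    mask = rng_images(1, shape=(24, 24), seed=8)[0] > 0.6
    empty = np.zeros_like(mask)
    np.testing.assert_array_equal(imops.reconstruct_components(mask, empty), empty)
    np.testing.assert_array_equal(imops.reconstruct_components(mask, mask), mask)
    once = imops.reconstruct_components(mask, empty | (mask & True))
    np.testing.assert_array_equal(imops.reconstruct_components(once, once), once)
    with pytest.raises(ValueError):
        imops.reconstruct_components(mask, np.zeros((5, 5), bool))


# ---------------------------------------------------------------------------
# adaptive SE size + morphology suite
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("M,N,eps,c,expected", [
    (1024, 1024, 0.01, 6, 61),
    (512, 512, 0.0, 3, 1),
    (1024, 800, 0.02, 0.05, 1),
])
def test_adaptive_se_size(M, N, eps, c, expected):
    assert imops.adaptive_se_size(M, N, eps, c) == expected


def test_fill_holes_closed_ring():
    ring = np.zeros((20, 20), bool)
    ring[5, 5:15] = ring[14, 5:15] = True
    ring[5:15, 5] = ring[5:15, 14] = True
    filled = imops.fill_holes(ring)
    assert filled[10, 10] and filled.sum() == 100
    np.testing.assert_array_equal(imops.fill_holes(filled), filled)


def test_largest_k_keeps_biggest_components():
    mask = np.zeros((40, 40), bool)
    mask[1:26, 1:21] = True    # area 500
    mask[30:35, 30:40] = True  # area 50
    out = imops.morph_suite(mask, "largest_k", k=1)
    assert out[1:26, 1:21].all() and not out[30:35, 30:40].any()
    np.testing.assert_array_equal(imops.largest_k(mask, 5), mask)


def test_convex_hull_idempotent_on_rectangle():
    rect = np.zeros((20, 20), bool)
    rect[4:12, 6:17] = True
    np.testing.assert_array_equal(imops.convex_hull(rect), rect)
    assert not imops.convex_hull(np.zeros((5, 5), bool)).any()


def test_prune_and_clean():
    mask = np.zeros((15, 15), bool)
    mask[7, 2:12] = True   # line with two endpoints
    mask[2, 2] = True      # isolated pixel
    pruned = imops.prune_spurs(mask, 1)
    assert pruned.sum() == mask.sum() - 3  # two line tips + isolated pixel
    cleaned = imops.clean_isolated(mask)
    assert not cleaned[2, 2] and cleaned[7, 5]


def test_disk_morphology_matches_footprint_ops():
    rng = np.random.default_rng(3)
    mask = ndimage.binary_dilation(rng.random((40, 40)) > 0.92)
    for n in (3, 5):
        se = skmorph.disk((n - 1) // 2)
        np.testing.assert_array_equal(
            imops.disk_dilate(mask, n),
            ndimage.binary_dilation(mask, structure=se))
    out = imops.disk_erode(np.ones((21, 21), bool), 9)
    inset = np.zeros((21, 21), bool)
    inset[4:17, 4:17] = True  # corners rounded by the disk, but inset by r=4
    assert not out[:4].any() and not out[:, :4].any() and out[10, 10]


def test_morph_suite_errors():
    mask = np.zeros((8, 8), bool)
    with pytest.raises(ValueError):
        imops.morph_suite(mask, "close")
    with pytest.raises(ValueError):
        imops.morph_suite(mask, "largest_k")
    with pytest.raises(ValueError):
        imops.morph_suite(mask, "warp")


def test_shapes_and_dtypes_preserved():
    for img in rng_images(5, shape=(17, 23), seed=11):
        mask = img > 0.5
        for op, kw in [("fill_holes", {}), ("skeletonize", {}),
                       ("convex_hull", {}), ("clean", {}),
                       ("close", {"se": ("disk", 3)}),
                       ("open", {"se": ("square", 3)})]:
            out = imops.morph_suite(mask, op, **kw)
            assert out.shape == mask.shape and out.dtype == bool
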