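"""LoG stage: conditioning, adaptive edge detection, region-mask pruning."""

import numpy as np
import pytest
from scipy import ndimage

from lungprior import imops, log_channel


def test_precondition_constant_and_impulse():
    const = np.full((32, 32), 0.5)
    np.testing.assert_allclose(log_channel.precondition(const), const)
    img = np.full((32, 32), 0.4)
    img[16, 16] = 1.0
    out = log_channel.precondition(img)
    assert out[16, 16] < 0.6  # impulse removed by the median filter


def test_precondition_min_filter_below_median():
    rng = np.random.default_rng(1)
    img = rng.uniform(0, 1, (32, 32))
    clahe = imops.clahe_enhance(img, (5, 5), 0.001, "uniform", 256)
    med = ndimage.median_filter(clahe, size=3, mode="nearest")
    out = log_channel.precondition(img)
    assert np.all(out <= med + 1e-12)


def test_enhance_rayleigh_contract():
    rng = np.random.default_rng(2)
    out = log_channel.enhance_rayleigh(rng.uniform(0, 1, (40, 40)))
    assert out.min() >= 0 and out.max() <= 1
    # a constant image stays constant (the stretch may shift its level)
    const = np.full((32, 32), 0.6)
    res = log_channel.enhance_rayleigh(const)
    assert float(res.max() - res.min()) == 0.0


def test_log_edges_adaptive_arithmetic():
    img = np.zeros((1024, 1024))
    img[0, 0] = 1.0
    _, sigma2, n, _ = log_channel.log_edges(img, 0.0081)
    assert sigma2 == pytest.approx(4.97664)
    assert n == int(np.ceil(sigma2 * 3)) * 2 + 1 == 31


def test_log_edges_closed_contour_around_dark_disk():
    rr, cc = np.mgrid[0:128, 0:128]
    img = np.where((rr - 64) ** 2 + (cc - 64) ** 2 <= 30 ** 2, 0.2, 0.8)
    edges, _, _, _ = log_channel.log_edges(img, 0.004)
    filled = imops.fill_holes(edges)
    assert filled.sum() > edges.sum()  # the contour encloses a region
    assert filled[64, 64]


def test_log_edges_constant_is_empty_with_warning():
    edges, sigma2, _, warnings = log_channel.log_edges(np.full((64, 64), 0.5), 0.0)
    assert not edges.any()
    assert sigma2 == 0.5 and warnings


def test_subtract_boundary_properties():
    rng = np.random.default_rng(3)
    edges = rng.random((32, 32)) > 0.8
    empty = np.zeros_like(edges)
    np.testing.assert_array_equal(log_channel.subtract_boundary(edges, empty), edges)
    np.testing.assert_array_equal(
        log_channel.subtract_boundary(edges, edges), empty)
    with pytest.raises(ValueError):
        log_channel.subtract_boundary(edges, np.zeros((4, 4), bool))


def test_subtract_boundary_disconnects_contour():
    ring = np.zeros((30, 30), bool)
    ring[5, 5:25] = ring[24, 5:25] = True
    ring[5:25, 5] = ring[5:25, 24] = True
    band = np.zeros_like(ring)
    band[:, 14:16] = True  # crosses the ring twice
    out = log_channel.subtract_boundary(ring, band)
    _, num = ndimage.label(out, structure=np.ones((3, 3)))
    assert num >= 2


def test_region_masks_geometry():
    full = np.ones((200, 200), bool)
    ribcage, shoulder, warnings = log_channel.build_region_masks(full, 0.02)
    assert not warnings
    assert ribcage.sum() < full.sum()           # erosion inset the frame
    assert not ribcage[0].any() and not ribcage[:, 0].any()
    # shoulder mask construction: complement restricted to the upper half
    half = 100
    assert not shoulder[half + 10:].any() or shoulder[half + 10:].sum() < shoulder[:half].sum()


def test_region_masks_empty_body():
    ribcage, shoulder, warnings = log_channel.build_region_masks(
        np.zeros((32, 32), bool), 0.01)
    assert not ribcage.any() and not shoulder.any() and warnings


def test_extract_lung_log_subset_chain():
    rng = np.random.default_rng(4)
    l1 = ndimage.binary_dilation(rng.random((48, 48)) > 0.9)
    ribcage = np.zeros_like(l1)
    ribcage[16:32, 16:32] = True
    shoulder = np.zeros_like(l1)
    shoulder[:6] = True
    no_sh, lung = log_channel.extract_lung_log(l1, ribcage, shoulder)
    assert np.all(lung <= no_sh) and np.all(no_sh <= l1)
    # with no shoulder seed, nothing is removed
    no_sh2, _ = log_channel.extract_lung_log(l1, ribcage, np.zeros_like(l1))
    np.testing.assert_array_equal(no_sh2, l1)


def test_refine_roi_contracts_on_phantom(stage1):
    art = stage1.log
    s1, s2, s3 = art.roi_s1, art.roi_s2, art.roi_s3
    assert np.all(s2 <= s1)                     # opening shrinks
    assert np.all(art.refined_edges <= art.lung_edges) or \
        np.array_equal(art.refined_edges, art.lung_edges)
    assert art.log_filter_n % 2 == 1 and art.log_filter_n >= 3
    assert art.sigma2 > 0


def test_refine_roi_empty_input():
    empty = np.zeros((32, 32), bool)
    s1, s2, s3, hull, refined, warnings = log_channel.refine_roi(
        empty, empty, empty, 0.01)
    assert not (s1.any() or s2.any() or s3.any() or hull.any() or refined.any())
    assert warnings


def test_phantom_hull_covers_lungs(stage1, stage1_truth):
    hull = stage1.log.roi_hull
    coverage = (hull & stage1_truth).sum() / stage1_truth.sum()
    assert coverage >= 0.90
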