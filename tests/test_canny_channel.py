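"""Canny stage: dual detection, pruning, lung separation, final mask."""

import numpy as np
import pytest
from scipy import ndimage

from lungprior import canny_channel, imops
from lungprior.params import default_params


def test_canny_pair_constant_empty():
    c1, c2 = canny_channel.canny_pair(np.full((64, 64), 0.5), 0.01)
    assert not c1.any() and not c2.any()


def test_canny_pair_scale_relation():
    p = default_params()
    assert p.canny2_sigma_c / p.canny1_sigma_c == pytest.approx(0.7)


def test_canny_pair_contour_encloses_dark_disk():
    rr, cc = np.mgrid[0:128, 0:128]
    # disk contrast placed inside the [0.4, 0.73] stretch window
    img = np.where((rr - 64) ** 2 + (cc - 64) ** 2 <= 30 ** 2, 0.45, 0.70)
    c1, c2 = canny_channel.canny_pair(img, 0.004)
    for edges in (c1, c2):
        filled = imops.fill_holes(edges)
        assert filled[64, 64] and filled.sum() > edges.sum()


def test_extract_lung_canny_selection():
    rng = np.random.default_rng(0)
    c1 = np.zeros((40, 40), bool)
    c1[5:10, 5:10] = True
    c2 = np.zeros_like(c1)
    c2[30:35, 30:35] = True
    log_clean = np.zeros_like(c1)
    log_clean[4:12, 4:12] = True  # hull covers only the first component
    hull, fused, warnings = canny_channel.extract_lung_canny(c1, c2, log_clean)
    assert not warnings
    assert fused[5:10, 5:10].all() and not fused[30:35, 30:35].any()
    assert np.all(fused <= (c1 | c2))
    # empty LoG set: warning + empty output
    hull2, fused2, w2 = canny_channel.extract_lung_canny(
        c1, c2, np.zeros_like(c1))
    assert not fused2.any() and w2


def test_prune_spine_and_saturation_contract_chain(stage1):
    art = stage1.canny
    assert np.all(art.canny_pruned <= art.canny_no_spine)
    assert np.all(art.canny_no_spine <= art.canny_fused)
    assert np.all(art.canny_fused <= (art.canny1 | art.canny2))


def test_prune_with_empty_masks_is_identity():
    rng = np.random.default_rng(1)
    cf = ndimage.binary_dilation(rng.random((48, 48)) > 0.9)
    flat = np.full((48, 48), 0.2)  # saturation mask will be empty (lo stretch)
    no_spine, sat, pruned = canny_channel.prune_spine_and_saturation(
        cf, np.zeros_like(cf), flat)
    np.testing.assert_array_equal(no_spine, cf)
    np.testing.assert_array_equal(pruned, cf & ~imops.reconstruct_components(cf, sat))


def test_separate_lungs_symmetric_phantom(stage1):
    art = stage1.canny
    labels, num = ndimage.label(art.minimal_mask, structure=np.ones((3, 3)))
    assert num >= 2
    sizes = np.sort(np.bincount(labels.ravel())[1:])[::-1][:2]
    assert 0.5 <= sizes[0] / sizes[1] <= 2.0


def test_separate_lungs_midline_fallback():
    icn = np.zeros((40, 40), bool)
    icn[10:20, 5:10] = True
    icn[10:20, 30:35] = True
    # spine mask covering everything leaves < 2 complement components
    spine_mask = np.ones_like(icn)
    out = canny_channel.separate_lungs(icn, spine_mask, icn, np.ones_like(icn))
    warnings = out[-1]
    assert any("midline" in w for w in warnings)


def test_separate_lungs_empty_edges_warns():
    empty = np.zeros((32, 32), bool)
    spine_mask = np.zeros_like(empty)
    spine_mask[:, 14:18] = True
    *_, minimal, ht, warnings = canny_channel.separate_lungs(
        empty, spine_mask, empty, np.ones_like(empty))
    assert not minimal.any() and warnings


def test_dilation_size_arithmetic():
    # per-side element sizes derived from the hull height
    ht = 800
    p = default_params()
    assert int(np.round(ht * p.lung_dilate_c)) == 5
    assert int(np.round(ht * p.lung_close_c)) == 4
    assert int(np.round(ht * p.lung_final_dilate_c)) == 24


def test_combine_rois_polygon_vertices_rectangles():
    """Abdominal polygon from hand-computed box corners of rectangular lungs."""
    cm = np.zeros((100, 100), bool)
    cm[20:60, 10:40] = True   # left lung box: tl=(10,20), br=(39,59)
    cm[25:70, 60:90] = True   # right lung box: tl=(60,25), br=(89,69)
    ilx = np.zeros_like(cm)
    ilx[21, 11] = ilx[26, 61] = True
    ml, poly, p1, predicted, warnings = canny_channel.combine_rois(ilx, cm)
    assert not warnings
    # vertices (x, y): A=(89, 25+(69-25)/2)=(89,47), B=(10, 20+(59-20)/2)=(10,39.5),
    # C=(39, 59), D=(60, 69); probe points inside/outside the quadrilateral
    assert poly[55, 50]            # central lower region inside
    assert not poly[30, 50]        # above the A-B line
    assert poly[48, 85]            # near vertex A, just inside
    # final mask covers the minimal mask
    assert np.all(cm <= predicted)


def test_combine_rois_empty_minimal_falls_back():
    empty = np.zeros((32, 32), bool)
    hull = np.zeros_like(empty)
    hull[8:24, 8:24] = True
    rib = np.ones_like(empty)
    *_, predicted, warnings = canny_channel.combine_rois(
        empty, empty, log_hull=hull, ribcage=rib)
    assert warnings
    np.testing.assert_array_equal(predicted, hull)
    # fully degenerate: everything empty
    *_, predicted2, w2 = canny_channel.combine_rois(empty, empty)
    assert not predicted2.any() and len(w2) >= 2


def test_final_mask_identity(stage1):
    art = stage1.canny
    np.testing.assert_array_equal(
        art.predicted_mask,
        imops.fill_holes(art.hull_minus_abdomen | art.minimal_mask))
    assert np.all(art.minimal_mask <= art.predicted_mask)
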