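"""Dual Canny extraction and the final predicted lung-field mask.

Two adaptive Canny variants (different scales and low thresholds) are run
on a high-contrast stretch of the enhanced radiograph.  Their union is
pruned to the hull of the LoG lung contours, then against the spine mask
and a saturation mask (over-exposed mediastinum/abdomen).  The remaining
edges are split into left and right lung sets using the complement of the
spine mask, regularized per side (dilation, two-component selection,
convex-hull reseeding, closing, dilation) and merged into a minimal lung
representation; combining it with the LoG contours, their convex hull and
an abdominal-corner polygon yields the final predicted mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from . import imops
from .params import HeuristicParams, default_params

__all__ = ["CannyArtifacts", "canny_pair", "extract_lung_canny",
           "prune_spine_and_saturation", "separate_lungs", "combine_rois",
           "run_canny_stage"]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class CannyArtifacts:
    canny1: np.ndarray
    canny2: np.ndarray
    log_hull: np.ndarray           # filled hull of the spine-free LoG edges
    canny_fused: np.ndarray        # hull-selected union of the two variants
    canny_no_spine: np.ndarray
    saturation_mask: np.ndarray
    canny_pruned: np.ndarray       # after spine + saturation pruning
    left_region: np.ndarray
    right_region: np.ndarray
    left_repr: np.ndarray          # regularized per-side lung representation
    right_repr: np.ndarray
    minimal_mask: np.ndarray       # filled union of the two sides
    hull_height: int
    combined_edges: np.ndarray     # LoG edges selected by the minimal mask
    combined_hull: np.ndarray
    abdomen_poly: np.ndarray
    hull_minus_abdomen: np.ndarray
    predicted_mask: np.ndarray     # final lung-field mask of the heuristic
    warnings: List[str] = field(default_factory=list)


def canny_pair(enhanced: np.ndarray, eps: float,
               params: HeuristicParams | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Two Canny variants on the high-contrast stretch of the input.

    Variant 1 uses low threshold ``max(floor, eps*10 - 0.4)`` at scale
    ``min(M,N)*eps``; variant 2 uses low threshold ``eps`` at 0.7 times
    that scale.  Both use the median-relative threshold convention.
    """
    p = params or default_params()
    base = imops.contrast_stretch(enhanced, *p.canny_stretch)
    M, N = base.shape
    s1 = min(M, N) * eps * p.canny1_sigma_c
    t1 = max(p.canny1_t1_floor, eps * p.canny1_t1_scale - p.canny1_t1_offset)
    c1 = imops.canny_adaptive(base, t1, p.canny_t2, s1)
    c2 = imops.canny_adaptive(base, eps, p.canny_t2,
                              s1 * p.canny2_sigma_c / p.canny1_sigma_c)
    return c1, c2


def extract_lung_canny(canny1: np.ndarray, canny2: np.ndarray,
                       log_edges_clean: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, List[str]]:
    """Select Canny components under the hull of the clean LoG edges."""
    warnings: List[str] = []
    union = np.asarray(canny1, bool) | np.asarray(canny2, bool)
    hull = imops.convex_hull(log_edges_clean)
    if not hull.any():
        warnings.append("no LoG contours: Canny selection empty")
        return hull, np.zeros_like(union), warnings
    return hull, imops.reconstruct_components(union, hull), warnings


def prune_spine_and_saturation(canny_fused: np.ndarray, spine_mask: np.ndarray,
                               enhanced: np.ndarray,
                               params: HeuristicParams | None = None
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Drop components on the spine, then components on the saturation mask.

    The saturation mask is a Rayleigh-CLAHE of the enhanced image stretched
    from an intensity floor tied to twice its mean (capped just below 1)
    and binarized at 0.5; it captures over-exposed spine/abdomen areas.
    """
    p = params or default_params()
    cf = np.asarray(canny_fused, bool)
    no_spine = cf & ~imops.reconstruct_components(cf, spine_mask)
    mu = float(imops.as_float_image(enhanced).mean())
    lo = 0.9 if 2 * mu > 1 else float(np.clip(2 * mu - 1, 0.0, p.saturation_lo_cap))
    c = p.saturation_clahe
    sat = imops.clahe_enhance(enhanced, c.tiles, c.clip, c.dist, c.bins, c.alpha)
    sat = imops.contrast_stretch(sat, lo, 1.0) if lo < 1.0 else sat
    sat_mask = sat >= p.saturation_binarize
    pruned = no_spine & ~imops.reconstruct_components(no_spine, sat_mask)
    return no_spine, sat_mask, pruned


def _two_side_regions(spine_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Left/right regions from the complemented spine mask (left = lower mean col)."""
    inv = ~np.asarray(spine_mask, bool)
    labels, num = ndimage.label(inv, structure=_EIGHT)
    if num >= 2:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        a, b = np.argsort(sizes)[::-1][:2]
        ma, mb = labels == a, labels == b
        if np.mean(np.nonzero(ma)[1]) <= np.mean(np.nonzero(mb)[1]):
            return ma, mb, False
        return mb, ma, False
    # fallback: split at the vertical midline
    half = spine_mask.shape[1] // 2
    left = inv.copy()
    left[:, half:] = False
    right = inv.copy()
    right[:, :half] = False
    return left, right, True


def _regularize_side(side_edges: np.ndarray, log_edges_clean: np.ndarray,
                     ht: int, p: HeuristicParams) -> np.ndarray:
    if not side_edges.any():
        return np.zeros_like(side_edges)
    n1 = max(1, int(np.round(ht * p.lung_dilate_c)))
    grown = imops.disk_dilate(side_edges, n1)
    grown = imops.largest_k(grown, 2)
    hull = imops.convex_hull(grown)
    repr_edges = imops.reconstruct_components(log_edges_clean, hull)
    if not repr_edges.any():
        repr_edges = grown
    closed = imops.disk_close(repr_edges, max(1, int(np.round(ht * p.lung_close_c))))
    return imops.disk_dilate(closed, max(1, int(np.round(ht * p.lung_final_dilate_c))))


def separate_lungs(canny_pruned: np.ndarray, spine_mask: np.ndarray,
                   log_edges_clean: np.ndarray, log_hull: np.ndarray,
                   params: HeuristicParams | None = None):
    """Split the pruned Canny edges by side and build the minimal lung mask.

    Returns ``(left_region, right_region, left_repr, right_repr,
    minimal_mask, hull_height, warnings)``.
    """
    p = params or default_params()
    warnings: List[str] = []
    icn = np.asarray(canny_pruned, bool)
    left_region, right_region, fell_back = _two_side_regions(spine_mask)
    if fell_back:
        warnings.append("spine mask does not split the frame: midline fallback")

    hull = np.asarray(log_hull, bool)
    if hull.any():
        rows = np.where(hull.any(axis=1))[0]
        ht = int(rows[-1] - rows[0] + 1)
    else:
        ht = icn.shape[0]
        warnings.append("empty LoG hull: using image height for scaling")

    if not icn.any():
        warnings.append("no Canny lung edges: minimal mask empty")
        z = np.zeros_like(icn)
        return left_region, right_region, z, z, z, ht, warnings

    left_edges = imops.reconstruct_components(icn, left_region)
    right_edges = imops.reconstruct_components(icn, right_region)
    left_repr = _regularize_side(left_edges, log_edges_clean, ht, p)
    right_repr = _regularize_side(right_edges, log_edges_clean, ht, p)
    if not left_repr.any() or not right_repr.any():
        warnings.append("one lung side empty: minimal mask from the other side")
    minimal = imops.fill_holes(left_repr | right_repr)
    return left_region, right_region, left_repr, right_repr, minimal, ht, warnings


def _component_bboxes_lr(mask: np.ndarray):
    """Bounding boxes of the two largest components, ordered left, right.

    Returns ((tlx, tly, blx, bly), (trx, try_, brx, bry)) with x = column of
    the top-left/bottom-right corners; a single component yields two equal
    boxes.
    """
    labels, num = ndimage.label(mask, structure=_EIGHT)
    if num == 0:
        return None
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    order = np.argsort(sizes)[::-1][:min(2, num)]
    boxes = []
    for lab in order:
        rs, cs = np.nonzero(labels == lab)
        boxes.append((int(cs.min()), int(rs.min()), int(cs.max()), int(rs.max()),
                      float(cs.mean())))
    if len(boxes) == 1:
        boxes = [boxes[0], boxes[0]]
    boxes.sort(key=lambda b: b[4])
    (tlx, tly, blx, bly, _), (trx, try_, brx, bry, _) = boxes
    return (tlx, tly, blx, bly), (trx, try_, brx, bry)


def combine_rois(log_edges_clean: np.ndarray, minimal_mask: np.ndarray,
                 log_hull: np.ndarray | None = None,
                 ribcage: np.ndarray | None = None,
                 params: HeuristicParams | None = None):
    """Final combination of LoG contours and the minimal Canny mask.

    The LoG contours selected by the minimal mask are hulled; a four-vertex
    polygon spanning the lower inner corners of the two per-lung bounding
    boxes (the likely abdominal area) is subtracted from the hull, and the
    result is ORed with the minimal mask and hole-filled.  Returns
    ``(combined_hull, poly_mask, hull_minus_abdomen, predicted, warnings)``.
    """
    warnings: List[str] = []
    ilx = np.asarray(log_edges_clean, bool)
    cm = np.asarray(minimal_mask, bool)
    empty = np.zeros_like(cm)
    if not cm.any():
        warnings.append("empty minimal mask: falling back to hull/ribcage")
        if log_hull is not None and ribcage is not None and \
                (np.asarray(log_hull, bool) & np.asarray(ribcage, bool)).any():
            fallback = imops.fill_holes(
                np.asarray(log_hull, bool) & np.asarray(ribcage, bool))
            return empty, empty, empty, fallback, warnings
        warnings.append("degenerate input: predicted mask empty")
        return empty, empty, empty, empty, warnings

    selected = imops.reconstruct_components(ilx, cm)
    ml = imops.convex_hull(selected if selected.any() else cm)
    boxes = _component_bboxes_lr(cm)
    (tlx, tly, blx, bly), (trx, try_, brx, bry) = boxes
    # vertices as (x, y) = (col, row)
    verts = [
        (brx, try_ + (bry - try_) / 2.0),
        (tlx, tly + (bly - tly) / 2.0),
        (blx, bly),
        (trx, bry),
    ]
    poly = np.zeros_like(cm)
    rr, cc = draw_polygon([v[1] for v in verts], [v[0] for v in verts],
                          shape=cm.shape)
    poly[rr, cc] = True
    p1 = ml & ~poly
    predicted = imops.fill_holes(p1 | cm)
    return ml, poly, p1, predicted, warnings


def run_canny_stage(enhanced: np.ndarray, eps: float,
                    log_edges_clean: np.ndarray, spine_mask: np.ndarray,
                    ribcage: np.ndarray | None = None,
                    params: HeuristicParams | None = None) -> CannyArtifacts:
    p = params or default_params()
    c1, c2 = canny_pair(enhanced, eps, p)
    hull, fused, warnings = extract_lung_canny(c1, c2, log_edges_clean)
    no_spine, sat_mask, pruned = prune_spine_and_saturation(
        fused, spine_mask, enhanced, p)
    (left_region, right_region, left_repr, right_repr,
     minimal, ht, w2) = separate_lungs(pruned, spine_mask,
                                       log_edges_clean, hull, p)
    ml, poly, p1, predicted, w3 = combine_rois(
        log_edges_clean, minimal, log_hull=hull, ribcage=ribcage, params=p)
    return CannyArtifacts(
        canny1=c1, canny2=c2, log_hull=hull, canny_fused=fused,
        canny_no_spine=no_spine, saturation_mask=sat_mask,
        canny_pruned=pruned, left_region=left_region,
        right_region=right_region, left_repr=left_repr,
        right_repr=right_repr, minimal_mask=minimal, hull_height=ht,
        combined_edges=imops.reconstruct_components(log_edges_clean, minimal),
        combined_hull=ml, abdomen_poly=poly, hull_minus_abdomen=p1,
        predicted_mask=predicted, warnings=warnings + w2 + w3)
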