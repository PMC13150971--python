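"""Spine modelling and removal of spine contours from the lung-edge set.

A crude vertical band is placed at the centroid of the lung-region hull;
bone edges are extracted from a bone-enhanced image (Rayleigh CLAHE, high
stretch, adaptive Canny), thinned to a skeleton, and intersected with the
band and hull.  A smoothing cubic spline ``col = f(row)`` is fitted to the
per-row mean columns of the skeleton, rasterized over the full image
height (linear extrapolation beyond the data span) and thickened into a
spine mask.  Edge components touching that mask are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy import ndimage
from scipy.interpolate import UnivariateSpline

from . import imops
from .params import HeuristicParams, default_params

__all__ = ["SpineArtifacts", "spine_band", "bone_edges", "spine_skeleton",
           "fit_spine_spline", "remove_spine", "run_spine_stage"]


@dataclass
class SpineArtifacts:
    band: np.ndarray               # vertical band at the hull centroid
    bone_edge_map: np.ndarray      # raw adaptive Canny of the bone image
    bone_skeleton: np.ndarray      # closed + skeletonized bone edges
    spine_pixels: np.ndarray       # skeleton restricted to band and hull
    spline_cols: np.ndarray | None  # fitted column per image row
    spline_raster: np.ndarray      # one-pixel-per-row rasterized spline
    spine_mask: np.ndarray         # thickened spline
    edges_no_spine: np.ndarray     # lung edges with spine contours removed
    warnings: List[str] = field(default_factory=list)


def spine_band(hull: np.ndarray,
               params: HeuristicParams | None = None
               ) -> tuple[np.ndarray, List[str]]:
    """Full-height vertical band centered at the hull's centroid column.

    The band half-width is ``band_width_frac`` of the hull bounding-box
    width (so the full width is twice that), clipped to the image.
    """
    p = params or default_params()
    h = np.asarray(hull, dtype=bool)
    warnings: List[str] = []
    if not h.any():
        warnings.append("empty hull: spine band empty")
        return np.zeros_like(h), warnings
    cols = np.where(h.any(axis=0))[0]
    width = cols[-1] - cols[0] + 1
    centroid_col = float(np.mean(np.nonzero(h)[1]))
    half = int(np.round(p.band_width_frac * width))
    c0 = max(0, int(np.round(centroid_col)) - half)
    c1 = min(h.shape[1], int(np.round(centroid_col)) + half)
    band = np.zeros_like(h)
    band[:, c0:c1] = True
    return band, warnings


def bone_edges(conditioned: np.ndarray, eps: float,
               params: HeuristicParams | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    """Adaptive Canny on a bone-enhanced image, plus its closed skeleton."""
    p = params or default_params()
    c = p.bone_clahe
    enhanced = imops.clahe_enhance(conditioned, c.tiles, c.clip, c.dist,
                                   c.bins, c.alpha)
    enhanced = imops.contrast_stretch(enhanced, *p.bone_stretch)
    M, N = enhanced.shape
    t1 = eps if p.bone_canny_t1 is None else p.bone_canny_t1
    sigma2 = min(M, N) * eps * p.bone_canny_sigma_c
    edge_map = imops.canny_adaptive(enhanced, t1, p.bone_canny_t2, sigma2)
    closed = imops.disk_close(
        edge_map, imops.adaptive_se_size(M, N, eps, p.bone_close_c))
    return edge_map, imops.skeletonize(closed)


def spine_skeleton(bone_skel: np.ndarray, band: np.ndarray,
                   hull: np.ndarray) -> np.ndarray:
    """Hole-fill and re-skeletonize the bone skeleton, AND with band and hull."""
    s = imops.skeletonize(imops.fill_holes(bone_skel))
    return s & np.asarray(band, bool) & np.asarray(hull, bool)


_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
            (0, 1), (1, -1), (1, 0), (1, 1)]


def _bfs_farthest(start, pixels):
    """Farthest pixel from ``start`` in an 8-connected pixel set, with parents."""
    parents = {start: None}
    frontier = [start]
    last = start
    while frontier:
        nxt = []
        for (r, c) in frontier:
            for dr, dc in _OFFSETS:
                q = (r + dr, c + dc)
                if q in pixels and q not in parents:
                    parents[q] = (r, c)
                    nxt.append(q)
        if nxt:
            last = nxt[-1]
        frontier = nxt
    return last, parents


def _longest_path(mask: np.ndarray) -> np.ndarray:
    """Longest geodesic path through one 8-connected skeleton component."""
    pixels = set(map(tuple, np.argwhere(mask)))
    if not pixels:
        return np.zeros_like(mask, dtype=bool)
    u, _ = _bfs_farthest(next(iter(pixels)), pixels)
    v, parents = _bfs_farthest(u, pixels)
    out = np.zeros_like(mask, dtype=bool)
    node = v
    while node is not None:
        out[node] = True
        node = parents[node]
    return out


def _band_extent(band: np.ndarray) -> tuple[int, int] | None:
    cols = np.where(np.asarray(band, bool).any(axis=0))[0]
    if cols.size == 0:
        return None
    return int(cols[0]), int(cols[-1])


def fit_spine_spline(spine_px: np.ndarray, band: np.ndarray,
                     params: HeuristicParams | None = None):
    """Smoothing cubic spline through the per-row mean spine columns.

    The fit uses only the connected component of the skeleton with the
    greatest vertical extent — the spine medial axis by construction —
    so that short bone fragments inside the band cannot drag the curve
    sideways.  The smoothing factor is relaxed until the RMS residual is
    at most ``spline_residual_px``.  The curve is rasterized one pixel per
    row over the full image height, extrapolating linearly beyond the
    fitted span and clamping to the band's column extent (the spine cannot
    leave its own band), then thickened by a disk of half the band width.
    With fewer than four pixels or rows, the band centerline is used and
    the mask is the central half-width of the band.  Returns
    ``(cols, raster, spine_mask, warnings)``.
    """
    p = params or default_params()
    px = np.asarray(spine_px, dtype=bool)
    b = np.asarray(band, dtype=bool)
    M, N = px.shape
    warnings: List[str] = []
    raster = np.zeros_like(px)
    extent = _band_extent(b)

    if px.any():
        labels, num = ndimage.label(px, structure=np.ones((3, 3), bool))
        if num > 1:
            sizes = np.bincount(labels.ravel(), minlength=num + 1)
            best, best_key = 1, (-1, -1)
            for lab in range(1, num + 1):
                rr = np.nonzero((labels == lab).any(axis=1))[0]
                key = (rr[-1] - rr[0] + 1, sizes[lab])
                if key > best_key:
                    best, best_key = lab, key
            px = labels == best
        # reduce the component to its longest geodesic path — the medial
        # axis of the spine — so rungs and branch arms cannot drag the
        # per-row means sideways
        path = _longest_path(px)
        if path.sum() >= 4 and np.count_nonzero(path.any(axis=1)) >= 4:
            px = path

    rows = np.where(px.any(axis=1))[0]
    degenerate = px.sum() < 4 or rows.size < 4
    if degenerate:
        warnings.append("sparse spine skeleton: falling back to band centerline")
        if extent is None:
            return None, raster, np.zeros_like(px), warnings
        c0, c1 = extent
        center = (c0 + c1) // 2
        quarter = max(1, (c1 - c0 + 1) // 4)
        raster[:, center] = True
        mask = np.zeros_like(px)
        mask[:, max(0, center - quarter):min(N, center + quarter + 1)] = True
        cols = np.full(M, float(center))
        return cols, raster, mask, warnings

    ys = rows.astype(np.float64)
    xs = np.array([np.mean(np.nonzero(px[r])[0]) for r in rows])

    def fit(y, x):
        k = min(3, y.size - 1)
        s = y.size * 16.0
        spl = None
        for _ in range(12):
            spl = UnivariateSpline(y, x, k=k, s=s)
            rms = float(np.sqrt(np.mean((spl(y) - x) ** 2)))
            if rms <= p.spline_residual_px:
                break
            s /= 4.0
        return spl

    spline = fit(ys, xs)
    # one robust trimming round: rows where the medial path escapes along a
    # branch (clavicle forks at the ends) are residual outliers
    resid = np.abs(spline(ys) - xs)
    mad = float(np.median(np.abs(resid - np.median(resid))))
    keep = resid <= max(5.0, 3.0 * 1.4826 * mad)
    if keep.sum() >= 4 and not keep.all():
        ys, xs = ys[keep], xs[keep]
        spline = fit(ys, xs)
    all_rows = np.arange(M, dtype=np.float64)
    cols = spline(all_rows)
    # constant-column extrapolation outside the fitted span: following the
    # end slope can shoot the curve across a lung at the apices
    y0, y1 = ys[0], ys[-1]
    cols[all_rows < y0] = float(spline(y0))
    cols[all_rows > y1] = float(spline(y1))
    if extent is not None:
        width = extent[1] - extent[0] + 1
        if float(cols.max() - cols.min()) > 0.5 * width:
            # a spine does not bow across half its own search band; a fit
            # with that much excursion is tracking bone clutter, so fall
            # back to the straight axis at the skeleton's median column
            warnings.append("implausible spine curvature: using median axis")
            cols = np.full(M, float(np.median(np.nonzero(px)[1])))
        cols = np.clip(cols, extent[0], extent[1])
    col_idx = np.clip(np.round(cols).astype(int), 0, N - 1)
    raster[np.arange(M), col_idx] = True
    width = (extent[1] - extent[0] + 1) if extent is not None else 0
    thick = max(1, int(np.round(p.spine_thicken_frac * width)))
    mask = imops.disk_dilate(raster, thick)
    return cols, raster, mask, warnings


def remove_spine(edges: np.ndarray, spine_mask: np.ndarray) -> np.ndarray:
    """Remove whole edge components that touch the spine mask."""
    e = np.asarray(edges, dtype=bool)
    return e & ~imops.reconstruct_components(e, spine_mask)


def run_spine_stage(conditioned: np.ndarray, hull: np.ndarray,
                    refined_edges: np.ndarray, eps: float,
                    params: HeuristicParams | None = None) -> SpineArtifacts:
    p = params or default_params()
    band, warnings = spine_band(hull, p)
    edge_map, bone_skel = bone_edges(conditioned, eps, p)
    spine_px = spine_skeleton(bone_skel, band, hull)
    cols, raster, mask, w2 = fit_spine_spline(spine_px, band, p)
    cleaned = remove_spine(refined_edges, mask)
    return SpineArtifacts(
        band=band, bone_edge_map=edge_map, bone_skeleton=bone_skel,
        spine_pixels=spine_px, spline_cols=cols, spline_raster=raster,
        spine_mask=mask, edges_no_spine=cleaned,
        warnings=warnings + w2)
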