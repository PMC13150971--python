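"""Laplacian-of-Gaussian lung-contour extraction and region-mask pruning.

The radiograph is contrast-conditioned (CLAHE, median and minimum filters,
then a Rayleigh-target CLAHE after a mid-range stretch), LoG-filtered at an
adaptive scale, and the significant zero-crossings are pruned in several
rounds: the body-boundary band disconnects contours crossing the body
outline; a shoulder mask removes clavicle/shoulder contours; a ribcage
mask selects the contours inside the thorax; and a convex-hull refinement
loop tightens the region of interest around the two lung fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy import ndimage

from . import imops
from .imops import EpsilonStats
from .params import HeuristicParams, default_params

__all__ = ["LogStageArtifacts", "precondition", "enhance_rayleigh",
           "log_edges", "subtract_boundary", "build_region_masks",
           "extract_lung_log", "refine_roi", "run_log_stage"]


@dataclass
class LogStageArtifacts:
    conditioned: np.ndarray        # CLAHE + median + min filtered input
    enhanced: np.ndarray           # Rayleigh-CLAHE of the stretched image
    sigma2: float                  # LoG variance actually used
    log_filter_n: int              # LoG kernel side (odd)
    log_edges: np.ndarray          # significant zero-crossings
    edges_no_boundary: np.ndarray  # after body-boundary subtraction
    ribcage_mask: np.ndarray
    shoulder_mask: np.ndarray
    edges_no_shoulder: np.ndarray
    lung_edges: np.ndarray         # contours selected by the ribcage mask
    roi_s1: np.ndarray
    roi_s2: np.ndarray
    roi_s3: np.ndarray
    roi_hull: np.ndarray           # convex hull of the refined ROI
    refined_edges: np.ndarray      # final LoG lung-contour set of this stage
    eps: EpsilonStats
    warnings: List[str] = field(default_factory=list)


def precondition(img: np.ndarray,
                 params: HeuristicParams | None = None) -> np.ndarray:
    """CLAHE, then 3x3 median, then 3x3 minimum (grayscale erosion)."""
    p = params or default_params()
    c = p.precondition_clahe
    out = imops.clahe_enhance(img, c.tiles, c.clip, c.dist, c.bins, c.alpha)
    out = ndimage.median_filter(out, size=3, mode="nearest")
    out = ndimage.grey_erosion(out, size=(3, 3), mode="nearest")
    return np.clip(out, 0.0, 1.0)


def enhance_rayleigh(conditioned: np.ndarray,
                     params: HeuristicParams | None = None) -> np.ndarray:
    """Mid-range stretch followed by Rayleigh-target CLAHE."""
    p = params or default_params()
    lo, hi = p.stretch_mid
    out = imops.contrast_stretch(conditioned, lo, hi)
    c = p.rayleigh_clahe
    return imops.clahe_enhance(out, c.tiles, c.clip, c.dist, c.bins, c.alpha)


def _zero_crossings(resp: np.ndarray) -> np.ndarray:
    """Mark the smaller-magnitude pixel of each horizontal/vertical sign change."""
    zc = np.zeros(resp.shape, dtype=bool)
    for axis in (0, 1):
        a = resp[:-1, :] if axis == 0 else resp[:, :-1]
        b = resp[1:, :] if axis == 0 else resp[:, 1:]
        change = (a * b) < 0
        a_smaller = np.abs(a) <= np.abs(b)
        if axis == 0:
            zc[:-1, :] |= change & a_smaller
            zc[1:, :] |= change & ~a_smaller
        else:
            zc[:, :-1] |= change & a_smaller
            zc[:, 1:] |= change & ~a_smaller
    return zc


def log_edges(img: np.ndarray, eps: float,
              params: HeuristicParams | None = None
              ) -> tuple[np.ndarray, float, int, List[str]]:
    """Adaptive-scale LoG edge detection by significant zero-crossings.

    The filter variance is ``min(M, N) * eps * c``; the kernel side is
    ``ceil(3 * variance) * 2 + 1``.  A zero-crossing is kept when its local
    response contrast (3x3 max minus min) exceeds a noise-referenced
    threshold: ``zc_rms_factor`` times the RMS of the LoG response over the
    image.  Filtered noise rarely swings more than about twice its RMS
    within a 3x3 window, while a genuine intensity step produces a response
    excursion far above it, so closed structure contours survive intact on
    clean and noisy images alike.
    """
    p = params or default_params()
    arr = imops.as_float_image(img)
    M, N = arr.shape
    warnings: List[str] = []
    sigma2 = min(M, N) * eps * p.log_sigma_c
    if sigma2 <= 0:
        warnings.append("zero LoG variance: floored to 0.5")
        sigma2 = 0.5
    n = int(np.ceil(sigma2 * 3)) * 2 + 1
    sigma = float(np.sqrt(sigma2))
    half = (n - 1) / 2
    resp = ndimage.gaussian_laplace(arr, sigma=sigma,
                                    truncate=max(half / sigma, 1.0),
                                    mode="nearest")
    zc = _zero_crossings(resp)
    if not zc.any():
        return np.zeros_like(zc), sigma2, n, warnings
    thr = p.log_zc_rms_factor * float(np.sqrt(np.mean(resp * resp)))
    contrast = (ndimage.maximum_filter(resp, size=3, mode="nearest")
                - ndimage.minimum_filter(resp, size=3, mode="nearest"))
    return zc & (contrast > thr), sigma2, n, warnings


def subtract_boundary(edges: np.ndarray, boundary_band: np.ndarray) -> np.ndarray:
    """Pixelwise removal of the body-boundary band from the edge image."""
    e = np.asarray(edges, dtype=bool)
    b = np.asarray(boundary_band, dtype=bool)
    if e.shape != b.shape:
        raise ValueError("edge/boundary shape mismatch")
    return e & ~b


def build_region_masks(body_mask: np.ndarray, eps: float,
                       params: HeuristicParams | None = None
                       ) -> tuple[np.ndarray, np.ndarray, List[str]]:
    """Ribcage mask and shoulder mask from the refined body blob.

    The ribcage mask is a large-disk closing of the body blob eroded by an
    adaptive disk; the shoulder mask is the complement of its upper half,
    dilated by a small adaptive disk (the lower half is empty before
    dilation).
    """
    p = params or default_params()
    m = np.asarray(body_mask, dtype=bool)
    warnings: List[str] = []
    if not m.any():
        warnings.append("empty body blob: region masks empty")
        return np.zeros_like(m), np.zeros_like(m), warnings
    M, N = m.shape
    n_close = max(1, int(np.round(min(M, N) * p.ribcage_close_c)))
    closed = imops.disk_close(m, n_close)
    ribcage = imops.disk_erode(
        closed, imops.adaptive_se_size(M, N, eps, p.ribcage_erode_c))
    upper = np.zeros_like(m)
    half = int(np.round(0.5 * M))
    upper[:half] = ~ribcage[:half]
    shoulder = imops.disk_dilate(
        upper, imops.adaptive_se_size(M, N, eps, p.shoulder_dilate_c))
    if not ribcage.any():
        warnings.append("ribcage mask vanished after erosion")
    return ribcage, shoulder, warnings


def extract_lung_log(edges: np.ndarray, ribcage: np.ndarray,
                     shoulder: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop shoulder-touching contours, then keep ribcage-touching ones."""
    no_shoulder = np.asarray(edges, bool) & ~imops.reconstruct_components(
        edges, shoulder)
    lung = imops.reconstruct_components(no_shoulder, ribcage)
    return no_shoulder, lung


def refine_roi(lung_edges: np.ndarray, edges_no_boundary: np.ndarray,
               ribcage: np.ndarray, eps: float,
               params: HeuristicParams | None = None):
    """Convex-hull ROI refinement.

    Re-collects edges under the hull of the lung contours, regularizes
    them (dilate, fill, close, open), re-seeds from an eroded ribcage
    mask, and reconstructs the lung contours under an eroded hull of the
    result.  Returns ``(s1, s2, s3, hull, refined_edges, warnings)``.
    """
    p = params or default_params()
    lf = np.asarray(lung_edges, dtype=bool)
    warnings: List[str] = []
    empty = np.zeros_like(lf)
    if not lf.any():
        warnings.append("no lung contours: ROI refinement skipped")
        return empty, empty, empty, empty, empty, warnings
    M, N = lf.shape
    d = imops.adaptive_se_size(M, N, eps, p.roi_dilate_close_c)
    hull0 = imops.convex_hull(lf)
    rec = imops.reconstruct_components(edges_no_boundary, hull0)
    s1 = imops.disk_close(imops.fill_holes(imops.disk_dilate(rec, d)), d)
    s2 = imops.disk_open(s1, d)
    seed = imops.disk_erode(
        ribcage, imops.adaptive_se_size(M, N, eps, p.roi_seed_erode_c))
    s3 = imops.reconstruct_components(s2, seed)
    if not s3.any():
        warnings.append("ROI vanished after ribcage seeding; keeping s2")
        s3 = s2
    hull = imops.convex_hull(s3)
    inner = imops.disk_erode(
        hull, imops.adaptive_se_size(M, N, eps, p.roi_hull_erode_c))
    refined = imops.reconstruct_components(lf, inner)
    if not refined.any():
        warnings.append("refined ROI empty; falling back to lung contours")
        refined = lf.copy()
    return s1, s2, s3, hull, refined, warnings


def run_log_stage(img: np.ndarray, body_mask: np.ndarray,
                  boundary_band: np.ndarray,
                  params: HeuristicParams | None = None) -> LogStageArtifacts:
    """Full LoG stage on the working-resolution radiograph."""
    p = params or default_params()
    conditioned = precondition(img, p)
    eps = imops.local_std_epsilon(conditioned)
    enhanced = enhance_rayleigh(conditioned, p)
    edges, sigma2, n, warnings = log_edges(enhanced, eps.epsilon, p)
    l1 = subtract_boundary(edges, boundary_band)
    ribcage, shoulder, w2 = build_region_masks(body_mask, eps.epsilon, p)
    no_shoulder, lung = extract_lung_log(l1, ribcage, shoulder)
    s1, s2, s3, hull, refined, w3 = refine_roi(lung, l1, ribcage,
                                               eps.epsilon, p)
    return LogStageArtifacts(
        conditioned=conditioned, enhanced=enhanced, sigma2=sigma2,
        log_filter_n=n, log_edges=edges, edges_no_boundary=l1,
        ribcage_mask=ribcage, shoulder_mask=shoulder,
        edges_no_shoulder=no_shoulder, lung_edges=lung,
        roi_s1=s1, roi_s2=s2, roi_s3=s3, roi_hull=hull,
        refined_edges=refined, eps=eps,
        warnings=warnings + w2 + w3)
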