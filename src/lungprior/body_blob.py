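"""Body-blob detection: foreground/background separation of the radiograph.

The chain is: rescale to a fixed working width, lift the dark regions with
a logarithmic transform and full-range contrast stretch, threshold at a
histogram valley on the 8-bit scale, clean the raw blob morphologically
(spur pruning, isolated-pixel cleaning, large-disk closing, hole filling,
largest-component selection), and finally extract the blob's one-pixel
boundary dilated by a 3x3 square — the band later subtracted from edge
images to disconnect contours that cross the body outline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
from skimage.transform import resize

from . import imops
from .imops import EpsilonStats
from .params import HeuristicParams, default_params

__all__ = ["BodyBlobArtifacts", "rescale_input", "enhance_body",
           "binarize_body", "refine_blob", "blob_boundary", "run_body_blob"]


@dataclass
class BodyBlobArtifacts:
    """All intermediates of the body-blob stage."""

    input_img: np.ndarray          # working-resolution radiograph
    enhanced: np.ndarray           # log-lifted, full-range-stretched image
    threshold: float               # valley threshold (on [0, 1])
    raw_mask: np.ndarray           # thresholded blob before cleanup
    body_mask: np.ndarray          # refined single-component body blob
    boundary_band: np.ndarray      # dilated one-pixel blob boundary
    eps: EpsilonStats
    warnings: List[str] = field(default_factory=list)


def rescale_input(raw: np.ndarray, width: int = 1024) -> np.ndarray:
    """Bilinearly rescale to ``width`` columns, preserving aspect ratio."""
    arr = imops.as_float_image(raw)
    M, N = arr.shape
    if N == width:
        return arr.copy()
    rows = max(8, int(np.round(width * M / N)))
    out = resize(arr, (rows, width), order=1, anti_aliasing=False,
                 preserve_range=True, mode="edge")
    return np.clip(out, 0.0, 1.0)


def enhance_body(img: np.ndarray) -> tuple[np.ndarray, EpsilonStats, List[str]]:
    """Log-lift dark regions, then stretch the result to [0, 1].

    The log image is min-max normalized before the full-range stretch so
    that the subsequent 8-bit-scale valley window is meaningful.
    """
    arr = imops.as_float_image(img)
    eps = imops.local_std_epsilon(arr)
    warnings: List[str] = []
    lifted = np.log(arr + eps.epsilon) if eps.epsilon > 0 else np.log1p(arr)
    span = float(lifted.max() - lifted.min())
    if span == 0.0:
        warnings.append("constant input: body enhancement is a no-op")
        return np.full_like(arr, float(arr.flat[0])), eps, warnings
    normalized = (lifted - lifted.min()) / span
    return imops.contrast_stretch(normalized, 0.0, 1.0), eps, warnings


def binarize_body(enhanced: np.ndarray,
                  params: HeuristicParams | None = None
                  ) -> tuple[np.ndarray, float]:
    """Threshold at the histogram valley; the (bright) body is foreground."""
    p = params or default_params()
    t = imops.histogram_valley_threshold(enhanced, p.histogram_range8)
    return imops.as_float_image(enhanced) >= t, t


def refine_blob(raw_mask: np.ndarray,
                params: HeuristicParams | None = None
                ) -> tuple[np.ndarray, List[str]]:
    """Prune, clean, close, fill and keep the largest component."""
    p = params or default_params()
    warnings: List[str] = []
    m = np.asarray(raw_mask, dtype=bool)
    if not m.any():
        warnings.append("empty raw blob: body not found")
        return m.copy(), warnings
    M, N = m.shape
    m = imops.prune_spurs(m, p.blob_prune_iters)
    m = imops.clean_isolated(m)
    n_close = max(1, int(np.round(min(M, N) * p.blob_close_c)))
    m = imops.disk_close(m, n_close)
    m = imops.fill_holes(m)
    m = imops.largest_k(m, 1)
    if not m.any():
        warnings.append("blob vanished during refinement")
    return m, warnings


def blob_boundary(body_mask: np.ndarray) -> np.ndarray:
    """One-pixel boundary of the blob, dilated by a 3x3 all-ones square."""
    m = np.asarray(body_mask, dtype=bool)
    if not m.any():
        return np.zeros_like(m)
    ring = m ^ imops.square_erode(m, 3)
    return imops.square_dilate(ring, 3)


def run_body_blob(raw: np.ndarray,
                  params: HeuristicParams | None = None) -> BodyBlobArtifacts:
    """Full body-blob stage on a raw radiograph."""
    p = params or default_params()
    img = rescale_input(raw, p.input_width)
    enhanced, eps, warnings = enhance_body(img)
    raw_mask, threshold = binarize_body(enhanced, p)
    body, w2 = refine_blob(raw_mask, p)
    warnings.extend(w2)
    band = blob_boundary(body)
    return BodyBlobArtifacts(
        input_img=img, enhanced=enhanced, threshold=threshold,
        raw_mask=raw_mask, body_mask=body, boundary_band=band,
        eps=eps, warnings=warnings)
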