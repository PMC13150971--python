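"""Image-processing primitives used throughout the edge-prior pipeline.

All intensity images are 2-D float arrays with values in [0, 1]; all masks
are 2-D boolean arrays.  Foreground connectivity is 8-connected, hole
connectivity 4-connected (thin diagonal edge contours must stay connected).

Disk structuring elements are specified by their *size* ``n`` — the
diameter of an all-ones disk inscribed in an ``n x n`` square, floored at
1.  Large-disk dilations and erosions are computed through the Euclidean
distance transform (thresholding the distance to the nearest foreground /
background pixel at radius ``(n - 1) / 2``), which is exact for Euclidean
disks and has cost independent of the disk size.  Erosion pads the border
with foreground, dilation with background, so closing an object that
touches the frame does not eat the frame margin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology as skmorph

__all__ = [
    "EpsilonStats",
    "as_float_image",
    "contrast_stretch",
    "local_std_epsilon",
    "histogram_valley_threshold",
    "clahe_enhance",
    "reconstruct_components",
    "adaptive_se_size",
    "disk_dilate",
    "disk_erode",
    "disk_close",
    "disk_open",
    "square_dilate",
    "square_erode",
    "fill_holes",
    "skeletonize",
    "convex_hull",
    "largest_k",
    "prune_spurs",
    "clean_isolated",
    "morph_suite",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class EpsilonStats:
    """Normalized average local standard deviation of an image.

    ``epsilon`` is the mean, over all pixels, of the population standard
    deviation of the (border-clipped) ``m x n`` window centered at each
    pixel, divided by the image maximum.  The window is the classic 3x3
    local-deviation neighborhood, which keeps the statistic on the scale
    of the image's fine texture and noise (about 0.005-0.03 for a
    conditioned radiograph) — the scale all adaptive filter variances and
    structuring-element sizes of the pipeline are calibrated to.  The
    statistic is 0 iff the image is constant and is invariant under
    multiplicative intensity rescaling.
    """

    epsilon: float
    window_rows: int
    window_cols: int


def as_float_image(img: np.ndarray) -> np.ndarray:
    """Validate and return a float64 image with values in [0, 1]."""
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError("image values must lie in [0, 1]")
    return np.clip(arr, 0.0, 1.0)


def _as_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D mask, got shape {arr.shape}")
    return arr.astype(bool, copy=False)


# ---------------------------------------------------------------------------
# intensity primitives
# ---------------------------------------------------------------------------

def contrast_stretch(img: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Linearly map [lo, hi] to [0, 1], clamping outside values."""
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError(f"invalid stretch bounds lo={lo}, hi={hi}")
    arr = as_float_image(img)
    return np.clip((arr - lo) / (hi - lo), 0.0, 1.0)


def local_std_epsilon(img: np.ndarray, window: tuple[int, int] = (3, 3)
                      ) -> EpsilonStats:
    """Average local window standard deviation, normalized by the maximum.

    Windows are centered at each pixel and clipped at the borders (no
    padding); even window sizes place the extra row/column toward larger
    indices.
    """
    arr = as_float_image(img)
    M, N = arr.shape
    m = max(1, min(int(window[0]), M))
    n = max(1, min(int(window[1]), N))

    vmax = float(arr.max())
    if vmax == 0.0 or float(arr.max() - arr.min()) == 0.0:
        return EpsilonStats(0.0, m, n)

    # integral images for windowed sums of x and x^2
    S = np.zeros((M + 1, N + 1))
    S2 = np.zeros((M + 1, N + 1))
    np.cumsum(np.cumsum(arr, axis=0), axis=1, out=S[1:, 1:])
    np.cumsum(np.cumsum(arr * arr, axis=0), axis=1, out=S2[1:, 1:])

    rows = np.arange(M)
    cols = np.arange(N)
    r0 = np.clip(rows - (m - 1) // 2, 0, M)
    r1 = np.clip(rows + m // 2 + 1, 0, M)
    c0 = np.clip(cols - (n - 1) // 2, 0, N)
    c1 = np.clip(cols + n // 2 + 1, 0, N)

    def window_sum(T: np.ndarray) -> np.ndarray:
        return (T[r1[:, None], c1[None, :]] - T[r0[:, None], c1[None, :]]
                - T[r1[:, None], c0[None, :]] + T[r0[:, None], c0[None, :]])

    cnt = (r1 - r0)[:, None] * (c1 - c0)[None, :]
    mean = window_sum(S) / cnt
    var = window_sum(S2) / cnt - mean * mean
    np.maximum(var, 0.0, out=var)
    eps = float(np.sqrt(var).mean() / vmax)
    return EpsilonStats(eps, m, n)


def histogram_valley_threshold(img: np.ndarray, range8=(130, 170)) -> float:
    """Valley (local histogram minimum) threshold on the 8-bit scale.

    Builds a 256-bin histogram, smooths it with a centered 5-bin moving
    average, and returns ``argmin / 255`` within ``range8`` (ties break to
    the lowest bin).  If the histogram is zero or monotone across the
    range, the midpoint of ``range8`` is returned.
    """
    a, b = int(range8[0]), int(range8[1])
    if not (0 <= a < b <= 255):
        raise ValueError(f"invalid 8-bit range {range8}")
    arr = as_float_image(img)
    levels = np.clip(np.round(arr * 255.0).astype(np.int64), 0, 255)
    hist = np.bincount(levels.ravel(), minlength=256).astype(np.float64)
    smoothed = np.convolve(hist, np.ones(5) / 5.0, mode="same")
    window = smoothed[a:b + 1]
    diffs = np.diff(window)
    if window.max() == 0.0 or np.all(diffs >= 0) or np.all(diffs <= 0):
        return (a + b) / 2.0 / 255.0
    return float(a + int(np.argmin(window))) / 255.0


def clahe_enhance(img: np.ndarray, tiles=(5, 5), clip: float = 0.01,
                  dist: str = "uniform", bins: int = 256,
                  alpha: float | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Per-tile histograms are clipped at ``clip`` (a fraction of the tile
    pixel count per bin; ``clip = 1`` disables clipping), the excess is
    redistributed uniformly, and the tile mapping is the inverse CDF of the
    target distribution: identity-CDF for ``uniform``, a Rayleigh CDF with
    scale ``alpha`` for ``rayleigh`` (the mapping is then renormalized to
    [0, 1]).  Pixel values are bilinearly interpolated between the four
    surrounding tile mappings.  A constant image is returned unchanged.
    """
    tr, tc = int(tiles[0]), int(tiles[1])
    if tr < 1 or tc < 1:
        raise ValueError("tile grid must be at least 1x1")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    dist = dist.lower()
    if dist not in ("uniform", "rayleigh"):
        raise ValueError(f"unknown distribution {dist!r}")
    if dist == "rayleigh" and alpha is None:
        raise ValueError("alpha is required for the rayleigh distribution")

    arr = as_float_image(img)
    if float(arr.max() - arr.min()) == 0.0:
        return arr.copy()
    M, N = arr.shape

    th = int(np.ceil(M / tr))
    tw = int(np.ceil(N / tc))
    pad_r, pad_c = tr * th - M, tc * tw - N
    padded = np.pad(arr, ((0, pad_r), (0, pad_c)), mode="edge")

    bin_idx = np.minimum((padded * bins).astype(np.int64), bins - 1)
    tile_r = np.arange(padded.shape[0]) // th
    tile_c = np.arange(padded.shape[1]) // tw
    flat = (tile_r[:, None] * tc + tile_c[None, :]) * bins + bin_idx
    hists = np.bincount(flat.ravel(), minlength=tr * tc * bins).astype(np.float64)
    hists = hists.reshape(tr * tc, bins)

    npix = float(th * tw)
    limit = max(clip * npix, 1.0)
    excess = np.clip(hists - limit, 0.0, None).sum(axis=1, keepdims=True)
    hists = np.minimum(hists, limit) + excess / bins

    cdf = np.cumsum(hists, axis=1) / npix
    if dist == "uniform":
        luts = cdf
    else:
        # inverse CDF of a Rayleigh(alpha) truncated to [0, 1]:
        # F(x) = (1 - exp(-x^2 / 2a^2)) / F1 with F1 = F_rayleigh(1),
        # so F^-1(c) = a * sqrt(-2 ln(1 - c * F1)) and F^-1(1) = 1 exactly
        f1 = -np.expm1(-1.0 / (2.0 * alpha ** 2))
        c = np.clip(cdf, 0.0, 1.0) * f1
        luts = alpha * np.sqrt(-2.0 * np.log1p(-np.minimum(c, 1 - 1e-15)))
    luts = luts.reshape(tr, tc, bins)

    # bilinear interpolation between tile-center mappings
    def axis_coords(size: int, ntiles: int, tsize: int):
        pos = (np.arange(size) - (tsize - 1) / 2.0) / tsize
        t0 = np.floor(pos).astype(np.int64)
        frac = pos - t0
        t0 = np.clip(t0, 0, ntiles - 1)
        t1 = np.clip(t0 + 1, 0, ntiles - 1)
        return t0, t1, frac

    r0, r1, fr = axis_coords(padded.shape[0], tr, th)
    c0, c1, fc = axis_coords(padded.shape[1], tc, tw)
    fr = np.clip(fr, 0.0, 1.0)[:, None]
    fc = np.clip(fc, 0.0, 1.0)[None, :]

    v00 = luts[r0[:, None], c0[None, :], bin_idx]
    v01 = luts[r0[:, None], c1[None, :], bin_idx]
    v10 = luts[r1[:, None], c0[None, :], bin_idx]
    v11 = luts[r1[:, None], c1[None, :], bin_idx]
    out = ((1 - fr) * ((1 - fc) * v00 + fc * v01)
           + fr * ((1 - fc) * v10 + fc * v11))
    return np.clip(out[:M, :N], 0.0, 1.0)


def canny_adaptive(img: np.ndarray, t1: float, t2: float,
                   sigma2: float) -> np.ndarray:
    """Canny edge detection with median-relative hysteresis thresholds.

    ``t1`` and ``t2`` are multipliers of the median gradient magnitude of
    the Gaussian-smoothed input (an absolute high threshold like 2 is not
    meaningful on a normalized gradient, so thresholds adapt to the image
    statistics instead).  Low/high are clamped to (0, 1]; if the ordering
    degenerates the low threshold is set to half the high one.  The
    Gaussian scale is ``sqrt(sigma2)`` (floored at 0.5).
    """
    from skimage import feature as skfeature
    from scipy.ndimage import gaussian_filter, sobel

    arr = as_float_image(img)
    sigma = float(np.sqrt(max(sigma2, 0.25)))
    smoothed = gaussian_filter(arr, sigma, mode="nearest")
    gx = sobel(smoothed, axis=1, mode="nearest")
    gy = sobel(smoothed, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    med = float(np.median(mag))
    if med <= 0:
        med = float(mag.mean())
    if med <= 0:
        return np.zeros(arr.shape, dtype=bool)
    low = float(np.clip(t1 * med, 1e-8, 1.0))
    high = float(np.clip(t2 * med, 1e-8, 1.0))
    if low >= high:
        low = 0.5 * high
    return skfeature.canny(arr, sigma=sigma, low_threshold=low,
                           high_threshold=high)


# ---------------------------------------------------------------------------
# binary morphology
# ---------------------------------------------------------------------------

def reconstruct_components(mask: np.ndarray, seed: np.ndarray) -> np.ndarray:
    """Union of the 8-connected components of ``mask`` that intersect ``seed``.

    Equivalent to morphological reconstruction by dilation with marker
    ``mask & seed`` inside ``mask``.  The result is a subset of ``mask``
    and the operation is idempotent.
    """
    m = _as_mask(mask)
    s = _as_mask(seed)
    if m.shape != s.shape:
        raise ValueError(f"shape mismatch: mask {m.shape} vs seed {s.shape}")
    marker = m & s
    if not marker.any():
        return np.zeros_like(m)
    labels, _ = ndimage.label(m, structure=_EIGHT)
    keep = np.unique(labels[marker])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def adaptive_se_size(M: int, N: int, eps: float, c: float) -> int:
    """Adaptive structuring-element size ``round(min(M, N) * eps * c)``, >= 1."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    if c <= 0:
        raise ValueError("c must be > 0")
    return max(1, int(np.round(min(M, N) * eps * c)))


def _disk_radius(n: int) -> float:
    return (max(1, int(n)) - 1) / 2.0


def disk_dilate(mask: np.ndarray, n: int) -> np.ndarray:
    """Dilation by an all-ones disk of diameter ``n`` (EDT-based)."""
    m = _as_mask(mask)
    r = _disk_radius(n)
    if r == 0.0 or not m.any():
        return m.copy()
    dist = ndimage.distance_transform_edt(~m)
    return dist <= r + 1e-9


def disk_erode(mask: np.ndarray, n: int) -> np.ndarray:
    """Erosion by an all-ones disk of diameter ``n`` (border = background).

    Pixels closer than the disk radius to the image frame are eroded, so
    eroding a full-frame mask yields a margin-inset rectangle.
    """
    m = _as_mask(mask)
    r = _disk_radius(n)
    if r == 0.0 or not m.any():
        return m.copy()
    padded = np.pad(m, 1, mode="constant", constant_values=False)
    dist = ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    return dist > r + 1e-9


def _disk_erode_border_fg(mask: np.ndarray, n: int) -> np.ndarray:
    # erosion with foreground padding: used inside closing so that objects
    # touching the frame are not eaten back from the border
    m = _as_mask(mask)
    r = _disk_radius(n)
    if r == 0.0 or not m.any() or m.all():
        return m.copy()
    dist = ndimage.distance_transform_edt(m)
    return dist > r + 1e-9


def disk_close(mask: np.ndarray, n: int) -> np.ndarray:
    return _disk_erode_border_fg(disk_dilate(mask, n), n)


def disk_open(mask: np.ndarray, n: int) -> np.ndarray:
    return disk_dilate(disk_erode(mask, n), n)


def square_dilate(mask: np.ndarray, n: int) -> np.ndarray:
    m = _as_mask(mask)
    if n <= 1:
        return m.copy()
    return ndimage.binary_dilation(m, structure=np.ones((n, n), bool))


def square_erode(mask: np.ndarray, n: int) -> np.ndarray:
    m = _as_mask(mask)
    if n <= 1:
        return m.copy()
    return ndimage.binary_erosion(m, structure=np.ones((n, n), bool),
                                  border_value=0)


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill 4-connected background regions not touching the border."""
    return ndimage.binary_fill_holes(_as_mask(mask))


def skeletonize(mask: np.ndarray) -> np.ndarray:
    return skmorph.skeletonize(_as_mask(mask))


def convex_hull(mask: np.ndarray) -> np.ndarray:
    """Filled convex hull of all foreground pixels (empty in, empty out)."""
    m = _as_mask(mask)
    if not m.any():
        return np.zeros_like(m)
    try:
        return skmorph.convex_hull_image(m)
    except Exception:
        # degenerate point sets (e.g. collinear pixels) fall back to the input
        return m.copy()


def largest_k(mask: np.ndarray, k: int) -> np.ndarray:
    """Keep the ``k`` largest 8-connected components (all, if fewer exist)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    m = _as_mask(mask)
    labels, num = ndimage.label(m, structure=_EIGHT)
    if num <= k:
        return m.copy()
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = np.argsort(sizes)[::-1][:k]
    return np.isin(labels, keep)


def _neighbor_count(mask: np.ndarray) -> np.ndarray:
    return ndimage.convolve(mask.astype(np.uint8), _EIGHT.astype(np.uint8),
                            mode="constant", cval=0) - mask.astype(np.uint8)


def prune_spurs(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Remove spur (end-point) pixels: foreground pixels with <= 1 neighbor."""
    m = _as_mask(mask).copy()
    for _ in range(max(0, int(iterations))):
        spurs = m & (_neighbor_count(m) <= 1)
        if not spurs.any():
            break
        m &= ~spurs
    return m


def clean_isolated(mask: np.ndarray) -> np.ndarray:
    """Remove isolated single pixels (no 8-neighbors)."""
    m = _as_mask(mask)
    return m & (_neighbor_count(m) > 0)


def morph_suite(mask: np.ndarray, op: str, se=None, k: int | None = None,
                iterations: int = 1) -> np.ndarray:
    """Dispatch table over the binary-morphology vocabulary.

    ``se`` is a ``(kind, n)`` pair with ``kind`` in {"disk", "square"};
    it is required for close/open/dilate/erode, ``k`` for ``largest_k``.
    """
    m = _as_mask(mask)
    if op in ("close", "open", "dilate", "erode"):
        if se is None:
            raise ValueError(f"op {op!r} requires a structuring element")
        kind, n = se
        if kind == "disk":
            fn = {"close": disk_close, "open": disk_open,
                  "dilate": disk_dilate, "erode": disk_erode}[op]
            return fn(m, n)
        if kind == "square":
            if op == "dilate":
                return square_dilate(m, n)
            if op == "erode":
                return square_erode(m, n)
            if op == "close":
                return square_erode(square_dilate(m, n), n)
            return square_dilate(square_erode(m, n), n)
        raise ValueError(f"unknown structuring element kind {kind!r}")
    if op == "fill_holes":
        return fill_holes(m)
    if op == "skeletonize":
        return skeletonize(m)
    if op == "convex_hull":
        return convex_hull(m)
    if op == "largest_k":
        if k is None:
            raise ValueError("op 'largest_k' requires k")
        return largest_k(m, k)
    if op == "prune":
        return prune_spurs(m, iterations)
    if op == "clean":
        return clean_isolated(m)
    raise ValueError(f"unknown morphological op {op!r}")
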