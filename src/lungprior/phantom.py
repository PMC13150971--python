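"""Seeded synthetic chest-radiograph phantoms with ground-truth lung masks.

The generator renders the anatomy the edge-prior heuristic exploits in a
posteroanterior chest film: a bright body blob on a dark background, two
dark elliptical lung fields, a bright vertical spine band (optionally with
a lateral sinusoidal bow), bright posterior rib arcs crossing the lungs,
clavicle streaks at the apices, and an optional bright corner text label,
followed by additive Gaussian noise.  The paired ground truth is the union
of the two lung ellipses, taken before noise.

Phantoms are deliberately simplified: there is no cardiac silhouette, no
diaphragm gradient, no pathology and no scatter model.  They exercise the
pipeline's structural assumptions, not its behavior on real films.

Two phantom *families* emulate different acquisition protocols for
cross-dataset experiments: family "A" uses the defaults below, family "B"
is globally brighter and noisier with more prominent ribs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Tuple

import numpy as np

__all__ = ["PhantomSpec", "generate_phantom", "generate_suite"]


@dataclass
class PhantomSpec:
    """Geometry and photometry of one synthetic radiograph.

    Positions and semi-axes are fractions of the image height (rows) and
    width (cols); intensities are in [0, 1].
    """

    size: Tuple[int, int] = (512, 512)
    background: float = 0.10
    # body ellipse: (center_row, center_col), (semi_row, semi_col)
    body_center: Tuple[float, float] = (0.54, 0.50)
    body_axes: Tuple[float, float] = (0.52, 0.43)
    body_intensity: float = 0.75
    # lung ellipses: one per side; tilt in degrees (clockwise positive)
    # the medial (mediastinal) lung borders stay clear of the paraspinal
    # band, as in a PA film
    lung_centers: Tuple[Tuple[float, float], ...] = ((0.46, 0.295), (0.46, 0.705))
    lung_axes: Tuple[Tuple[float, float], ...] = ((0.26, 0.118), (0.26, 0.118))
    # apices lean toward the midline as in a PA film (left: +, right: -)
    lung_tilts: Tuple[float, float] = (10.0, -10.0)
    lung_intensity: float = 0.25
    # spine band
    spine_col: float = 0.5
    spine_width_frac: float = 0.12
    spine_intensity: float = 0.90
    spine_bow_amp: float = 0.0        # lateral sinusoidal bow, fraction of width
    spine_top: float = 0.08
    vertebra_period: float = 0.055    # vertebral body + disc spacing, fraction of rows
    vertebra_contrast: float = 0.08   # body/disc intensity modulation depth
    # ribs
    ribs_per_side: int = 7
    rib_thickness: float = 0.010      # fraction of rows
    rib_intensity: float = 0.65
    # clavicles
    clavicles: bool = True
    clavicle_intensity: float = 0.70
    # corner label artifact
    corner_label: bool = True
    label_intensity: float = 1.0
    # photometry
    noise_sigma: float = 0.02
    contrast_scale: float = 1.0       # global multiplicative jitter
    seed: int = 0


def _grid(shape):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return rr.astype(np.float64), cc.astype(np.float64)


def _ellipse_mask(shape, center_rc, axes_rc, tilt_deg=0.0):
    M, N = shape
    rr, cc = _grid(shape)
    cr, ccol = center_rc[0] * M, center_rc[1] * N
    ar, ac = axes_rc[0] * M, axes_rc[1] * N
    t = np.deg2rad(tilt_deg)
    dr, dc = rr - cr, cc - ccol
    u = dr * np.cos(t) - dc * np.sin(t)
    v = dr * np.sin(t) + dc * np.cos(t)
    return (u / ar) ** 2 + (v / ac) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one phantom; returns ``(image, lung_mask)``.

    Deterministic for a fixed spec (including its seed).  Raises if a lung
    ellipse leaves the body ellipse.
    """
    M, N = spec.size
    rng = np.random.default_rng(spec.seed)
    img = np.full((M, N), spec.background, dtype=np.float64)

    body = _ellipse_mask((M, N), spec.body_center, spec.body_axes)
    img[body] = spec.body_intensity

    lungs = np.zeros((M, N), dtype=bool)
    lung_masks = []
    for center, axes, tilt in zip(spec.lung_centers, spec.lung_axes, spec.lung_tilts):
        lm = _ellipse_mask((M, N), center, axes, tilt)
        if (lm & ~body).any():
            raise ValueError("invalid geometry: lung ellipse outside the body")
        lung_masks.append(lm)
        lungs |= lm
    img[lungs] = spec.lung_intensity

    # spine band (drawn over everything in its column range, rows below top)
    rr, cc = _grid((M, N))
    half_w = 0.5 * spec.spine_width_frac * N
    center_cols = spec.spine_col * N + spec.spine_bow_amp * N * np.sin(
        np.pi * rr[:, 0] / M)
    spine = (np.abs(cc - center_cols[:, None]) <= half_w) & (rr >= spec.spine_top * M)
    # vertebral bodies: periodic bright segments separated by darker disc gaps
    if spec.vertebra_period > 0 and spec.vertebra_contrast > 0:
        phase = np.cos(2 * np.pi * rr / (spec.vertebra_period * M))
        vert = spec.spine_intensity + 0.5 * spec.vertebra_contrast * (phase - 1.0)
    else:
        vert = np.full_like(rr, spec.spine_intensity)
    img[spine] = np.maximum(img[spine], vert[spine])

    # posterior rib arcs: elliptical bands swept across each lung
    thick = max(1.5, spec.rib_thickness * M)
    for lm, (lc, lcol), tilt in zip(lung_masks, spec.lung_centers, spec.lung_tilts):
        rows_span = np.where(lm.any(axis=1))[0]
        if rows_span.size == 0 or spec.ribs_per_side <= 0:
            continue
        top, bot = rows_span[0], rows_span[-1]
        for i in range(spec.ribs_per_side):
            frac = (i + 1) / (spec.ribs_per_side + 1)
            row_i = top + frac * (bot - top)
            # arc: band of an ellipse centered above-and-medial of the rib row
            a_r = 0.22 * M
            a_c = 0.20 * N
            d = np.sqrt(((rr - (row_i - a_r)) / a_r) ** 2
                        + ((cc - lcol * N) / a_c) ** 2)
            band = np.abs(d - 1.0) * a_r <= thick / 2.0
            sel = band & lm
            img[sel] = np.maximum(img[sel], spec.rib_intensity)

    if spec.clavicles:
        for lc, lcol in [c for c in spec.lung_centers]:
            rows_c = 0.22 * M + 0.06 * M * np.sin(
                np.pi * (cc[0] / N - lcol) / 0.4)
            sel = (np.abs(rr - rows_c[None, :]) <= max(1.0, 0.006 * M)) \
                & (np.abs(cc - lcol * N) <= 0.16 * N)
            sel &= body
            img[sel] = np.maximum(img[sel], spec.clavicle_intensity)

    if spec.corner_label:
        # crude glyph block in the top-left background corner
        r0, c0 = int(0.03 * M), int(0.03 * N)
        h, w = int(0.035 * M), int(0.018 * N)
        for j in range(3):
            cs = c0 + j * int(1.8 * w)
            img[r0:r0 + h, cs:cs + w] = spec.label_intensity
            img[r0:r0 + 2, cs:cs + w] = spec.label_intensity

    img = np.clip(0.5 + (img - 0.5) * spec.contrast_scale, 0.0, 1.0)
    truth = lungs.copy()
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0), truth


_FAMILY_CODE = {"A": 1, "B": 2}


def _family_spec(family: str) -> PhantomSpec:
    if family == "A":
        return PhantomSpec()
    if family == "B":
        return PhantomSpec(
            background=0.24,
            body_intensity=0.68,
            lung_intensity=0.32,
            rib_intensity=0.72,
            spine_intensity=0.85,
            noise_sigma=0.035,
        )
    raise ValueError(f"unknown phantom family {family!r}")


def generate_suite(n: int, base_seed: int = 0, family: str = "A",
                   size: Tuple[int, int] | None = None
                   ) -> List[tuple[np.ndarray, np.ndarray]]:
    """Generate ``n`` phantoms with per-seed jitter of geometry and contrast."""
    if n < 1:
        raise ValueError("n must be >= 1")
    base = _family_spec(family)
    if size is not None:
        base = replace(base, size=tuple(size))
    out = []
    for i in range(n):
        rng = np.random.default_rng([int(base_seed), i, _FAMILY_CODE[family]])
        jit = rng.uniform(-1.0, 1.0, size=16)
        spec = replace(
            base,
            body_center=(base.body_center[0] + 0.01 * jit[0],
                         base.body_center[1] + 0.01 * jit[1]),
            lung_centers=tuple(
                (c[0] + 0.012 * jit[2 + 2 * s], c[1] + 0.008 * jit[3 + 2 * s])
                for s, c in enumerate(base.lung_centers)),
            lung_axes=tuple(
                (a[0] * (1 + 0.07 * jit[6 + 2 * s]), a[1] * (1 + 0.07 * jit[7 + 2 * s]))
                for s, a in enumerate(base.lung_axes)),
            lung_tilts=(base.lung_tilts[0] + 3.0 * jit[10],
                        base.lung_tilts[1] + 3.0 * jit[11]),
            spine_col=base.spine_col + 0.008 * jit[12],
            spine_bow_amp=0.006 * (1 + jit[13]),
            contrast_scale=base.contrast_scale * (1 + 0.06 * jit[14]),
            noise_sigma=base.noise_sigma * (1 + 0.2 * jit[15]),
            seed=int(rng.integers(0, 2 ** 31 - 1)),
        )
        out.append(generate_phantom(spec))
    return out
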