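# Methods

This note records the scientific and numerical choices behind
`lungprior`: what the pipeline computes, which knobs matter, what the
synthetic phantoms do and do not emulate, and where the design was
genuinely open.

## The adaptive deviation statistic ε

Nearly every scale in Stage 1 — LoG and Canny filter variances,
morphological structuring-element sizes — is derived as
`min(M, N) · ε · c` from one statistic of the image being processed:

> ε = mean over all pixels of the population standard deviation of the
> 3×3 window centered at the pixel (windows clipped at borders), divided
> by the image maximum.

This is the field-standard local-deviation map (MATLAB `stdfilt`-style),
averaged and normalized so that ε is dimensionless, scale-invariant
(multiplying the image by a constant leaves it unchanged) and zero
exactly for constant images. On a conditioned radiograph ε is about
0.005–0.03, which puts the working points where the pipeline's
coefficients are calibrated: at N = 1024 and ε ≈ 0.008 the LoG variance
is σ² ≈ 5 with a 31×31 kernel, and the ribcage erosion element
(c = 6) is ≈ 50 px. Window definitions: even window sizes place the
extra row/column toward larger indices; borders clip rather than pad.
An alternative reading with half-image windows was evaluated and
rejected: it yields ε two orders of magnitude larger on any realistic
film, which inflates every adaptive element beyond the image frame and
degenerates the cascade.

## Contrast conditioning

* **CLAHE** is implemented natively (tile histograms, clip-limit as a
  fraction of the tile pixel count with uniform redistribution of the
  excess, bilinear interpolation between the four surrounding tile
  mappings). The clip value 1.0 disables clipping. Two target
  distributions are supported: uniform (mapping = tile CDF) and
  Rayleigh with scale α, implemented as the inverse CDF of a Rayleigh
  *truncated to [0, 1]* — `F⁻¹(c · F(1))` — so the mapping is exactly 1
  at CDF 1 and the output spans the unit interval. Normalizing by the
  unbounded inverse CDF instead compresses the whole image into a small
  sub-range (measured: [0, 0.33] at α = 0.7) and starves the downstream
  mid-range stretches; the truncated form avoids that failure.
  A globally constant image is returned unchanged under any settings.
* **Stretch windows** follow the pipeline configuration
  (`HeuristicParams`): [0.05, 0.95] before the Rayleigh CLAHE,
  [0.4, 1.0] for the bone image, [0.4, 0.73] for the Canny input, and a
  mean-tied window for the saturation mask (floor 0.9 when 2·mean > 1,
  else clamp(2·mean − 1, 0, 0.89); binarized at 0.5).

## Edge detection

* **LoG contours** are zero-crossings of the Gaussian-Laplacian response
  at σ² = min(M,N)·ε·0.6 (kernel side `ceil(3σ²)·2+1`, always odd and
  ≥ 3; σ² floored at 0.5 for degenerate inputs). A crossing is kept when
  its local response contrast (3×3 max − min) exceeds 2× the RMS of the
  response over the image. Filtered noise rarely swings beyond twice its
  RMS inside a 3×3 window, while genuine intensity steps exceed it by an
  order of magnitude, so the rule suppresses noise squiggles without
  breaking closed structure contours; on noise-free images the threshold
  is tiny relative to the structural response and everything survives.
  A percentile-of-|response|-at-crossings rule was tried first and
  discarded: the response at a crossing is near zero by definition, so
  that threshold sits below the noise floor and keeps everything.
* **Canny thresholds** are specified as multipliers (T1, T2) of the
  median gradient magnitude of the Gaussian-smoothed input (an absolute
  high threshold of 2 is not meaningful on a normalized gradient). Low
  and high are clamped to (0, 1]; if ordering degenerates, low is set to
  half of high. The two lung-field variants share one contrast window
  and differ in scale (σ² vs 0.7·σ²) and low threshold
  (max(0.01, 10ε − 0.4) vs ε); the bone variant uses σ² = min(M,N)·ε·0.67.

## Morphology conventions

* Foreground is 8-connected, holes are 4-connected (thin diagonal
  contours must stay connected).
* A disk of *size n* is the all-ones disk inscribed in an n×n square,
  floored at 1. Large-disk dilation/erosion go through the Euclidean
  distance transform (exact for Euclidean disks, cost independent of
  disk size). Standalone erosion treats the frame border as background
  (eroding a full frame insets it); the erosion inside *closing* pads
  with foreground so closing cannot eat border-touching objects.
* `reconstruct(mask, seed)` selects whole 8-connected components of
  `mask` that intersect `seed` — equivalent to binary morphological
  reconstruction by dilation with marker `mask ∧ seed` — and is the
  workhorse of all pruning steps (shoulder, ribcage, spine, saturation,
  left/right separation).
* The histogram-valley threshold builds a 256-bin histogram on the 8-bit
  scale, smooths with a centered 5-bin moving average, and takes the
  argmin within [130, 170] (ties → lowest bin; zero or monotone
  histogram → the midpoint, 150/255).

## Spine model

The spine search band is centered at the centroid column of the lung-ROI
convex hull with half-width 0.15× the hull's bounding-box width. Bone
edges (Rayleigh CLAHE α = 0.2, stretch [0.4, 1], adaptive Canny, closing,
skeletonization, hole-fill, re-skeletonization) are intersected with the
band and hull. The medial axis is then the *longest geodesic path*
(double-BFS skeleton diameter) through the component with the greatest
vertical extent — vertebral "rungs" and clavicle fork arms on the
skeleton otherwise drag the fit sideways. A smoothing cubic spline
`col = f(row)` is fitted to the per-row mean columns, relaxing the
smoothing factor until the RMS residual is ≤ 2 px, with one robust
trimming round (rows beyond 3 MAD-scaled sigmas, floor 5 px, are dropped
and the spline refit). The curve is rasterized one pixel per row over
the full image height with constant-column extrapolation beyond the
fitted span, clamped to the band, and a fitted curve whose total lateral
excursion exceeds half the band width — more than a spine plausibly
bows — falls back to the straight axis at the skeleton's median column.
Thickening uses a disk of half the band width. With fewer than four
skeleton pixels or rows, the band centerline at half band width is the
fallback. Edge components touching the thickened mask are removed
wholesale; this trades a small risk of deleting medial lung contours for
reliable spine suppression, and the final mask construction (convex
hull + per-side regularization) recovers from moderate losses.

## Final mask assembly

Pruned Canny edges are split by the complement of the spine mask into
left/right regions (largest two components; left = smaller mean column;
fallback: vertical midline split). Each side is dilated
(disk ≈ 0.006·hull-height), reduced to its two largest components,
hulled, used to reselect LoG contours, closed (0.005·ht) and dilated
(0.03·ht); the filled union is the minimal lung mask. The convex hull of
the LoG contours selected by that mask, minus a four-vertex abdominal
polygon spanning the lower inner corners of the two per-lung bounding
boxes, ORed with the minimal mask and hole-filled, is the predicted
lung-field mask. Degenerate inputs fall back (hull ∧ ribcage, or empty
with a warning) — Stage 1 never raises on image content.

## Synthetic phantoms

The generator renders the anatomy the heuristic exploits: bright body
ellipse on dark background, two dark lung ellipses whose apices lean
toward the midline (+10°/−10°) and whose medial borders stay clear of
the paraspinal band (centers ±0.205·N, column semi-axes 0.118·N), a
vertical spine band (width 0.12·N, intensity 0.9) with periodic
vertebral modulation (period 0.055·M, depth 0.08) and optional
sinusoidal bow, seven rib arcs per side (intensity 0.65) clipped to the
lung interiors, clavicle streaks, an optional corner label block, and
additive Gaussian noise (σ = 0.02), clamped to [0, 1]. Ground truth is
the union of the lung ellipses before noise. Family "A" is the default;
family "B" emulates a different acquisition protocol (over-penetrated
background 0.24, body 0.68, lungs 0.32, heavier noise 0.035, more
prominent ribs) and exists for cross-dataset transfer experiments. The
suite jitters geometry, tilt, bow and contrast per seed.

Phantoms deliberately omit cardiac silhouette, diaphragm gradients,
scatter, pathology and soft-tissue texture. Passing the phantom gates
therefore demonstrates that the cascade's logic behaves as designed
under its structural assumptions — not clinical-grade performance on
real films, which depends on contrast behavior the phantoms do not
model.

## Training harness

The network layer is a compact reverse-mode autodiff engine on numpy
(float32): same-padded convolutions by shifted einsum, ReLU, sigmoid,
2×2 max-pooling, nearest-neighbor upsampling, channel concatenation and
numerically safe logit binary cross-entropy, with a standard Adam
optimizer. Five architecture families share one parameterization (depth,
base filters) and one contract (input (B,3,H,W) → single-logit plane):
plain, residual, attention-gated, nested dense-skip, and attention+dense
blocks. He-normal initialization is seeded; batch order is a seeded
per-epoch shuffle; all operations are deterministic on CPU, so a fixed
seed reproduces weights bit for bit. The 1×1 mixer initializes to the
identity on the grayscale plane so step-0 logits equal the grayscale
baseline for every channel combination — a testable contract. Defaults
follow the standard configuration (Adam, lr 1e-4, batch 4, 50 epochs,
256×256 inputs, prediction threshold 0.5 on sigmoid outputs);
`max_steps` caps training for reduced-scale runs. Hold-out splits
reserve round(0.2·n) images under a seeded shuffle; k-fold partitions
the remainder into folds differing by at most one; per-image metrics are
macro-averaged, with the empty-vs-empty convention scoring 1.0.

## Problem sizes

The test suite and the acceptance script run at deliberately small
scale, chosen to exercise every code path on one CPU core: the Stage-1
gate uses 20 jittered 512×512 phantoms (processed at the 1024-column
working width); the training smoke test uses 8 phantoms at 64×64 with a
depth-3/8-filter U-Net for 200 steps; transfer experiments use 8 + 6
phantoms and 100 steps; the ablation sweep runs all 16 combinations at
2 steps each to verify the table contract. Full-scale experiments
(50 epochs at 256×256 on real datasets) use the same code paths through
the CLI or estimators.

## Known limitations

* The spine-removal step deletes whole edge components; on films (or
  jittered phantoms) where medial lung contours enter the paraspinal
  band it can remove rib-strip contours, which downstream hulling only
  partly recovers. The per-seed dice spread of the phantom gate largely
  reflects this.
* The heuristic assumes a posteroanterior orientation (spine central,
  lungs lateral, body upright); lateral views, heavy rotation, or
  multi-body-part images are out of scope.
* The numpy network engine favors determinism and portability over
  speed; it is intended for the reduced-scale protocols above, not for
  full-resolution training runs, which would be slow without a GPU
  framework.
* Grayscale (non-binary) morphological reconstruction is not
  implemented; component selection covers every use in the pipeline.
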