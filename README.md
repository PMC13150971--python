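# lungprior

Training-free structural edge priors and early-fusion deep segmentation of
lung fields in chest radiographs.

Automatic lung-field segmentation (LFS) on posteroanterior chest films is
a standard preprocessing step for computer-aided diagnosis, but models
trained on one dataset often degrade on films from another scanner or
hospital. `lungprior` implements a two-stage approach to make segmentation
networks more generalizable:

1. **Stage 1 — edge-prior extraction (no training, no ground truth).**
   A cascade of classical operations turns one grayscale radiograph into
   four structural prior channels: two adaptive Canny edge variants
   (`cn1`, `cn2`), a pruned Laplacian-of-Gaussian lung-contour
   representation (`log`), and a heuristic predicted lung mask (`pm`).
   The cascade detects the body blob, conditions the image with CLAHE
   (uniform and Rayleigh targets), extracts LoG zero-crossing contours at
   an adaptive scale σ² = min(M,N)·ε·c driven by the image's normalized
   local deviation ε, prunes contours with morphological-reconstruction
   masks (body boundary, shoulder, ribcage), models and removes the spine
   (vertical band → bone skeleton → smoothing spline → thickened mask),
   and fuses dual Canny contours into left/right lung regions.

2. **Stage 2 — early fusion and training.** The five aligned planes
   (grayscale `Io` + the four priors, 256×256) pass through a binary
   channel selection m ∈ {0,1}⁴ and a learnable 1×1 mixer that projects
   5 → 3 planes. With its default initialization (weight 1.0 on `Io`,
   zeros elsewhere) the mixer reproduces the plain radiograph exactly, so
   every configuration starts from the grayscale baseline. A configurable
   encoder–decoder family (U-Net, attention, nested/dense-skip, residual
   variants) trains on logit binary cross-entropy with Adam. Since `Io`
   is always active and each prior is on or off, there are 2⁴ = 16
   channel combinations; the harness sweeps all of them and reports
   dice / IoU / accuracy / precision / recall deltas against the baseline,
   under hold-out, 5-fold and cross-dataset protocols.

The package ships a seeded synthetic-phantom generator (bright body blob,
dark lung ellipses, vertebral spine band, rib arcs, clavicles, corner
label, noise — with paired ground-truth masks) that provides the full test
surface without any external data. Real datasets are consumed through a
generic image+mask directory loader (8/16-bit PNG/TIFF).

## Worked example

```python
import numpy as np
import lungprior as lp
from skimage.transform import resize

img, truth = lp.generate_phantom(lp.PhantomSpec(seed=0))
result = lp.run_stage1(img)                   # full Stage-1 heuristic
pred = result.predicted_mask                  # heuristic lung mask (no training)
truth_hi = resize(truth.astype(float), pred.shape, order=0,
                  anti_aliasing=False, preserve_range=True) > 0.5
report = lp.pixel_metrics(pred, truth_hi)
print(f"predicted-mask dice: {report.dice:.3f}  IoU: {report.iou:.3f}")
print(f"channel stack shape: {result.channels.stack().shape}")
```

prints

```
predicted-mask dice: 0.817  IoU: 0.691
channel stack shape: (5, 256, 256)
```

i.e. the training-free heuristic alone recovers the phantom's lung fields
with dice 0.82, and the five-plane channel stack is ready for Stage 2.
Training a fusion model on such stacks:

```python
from lungprior import EdgePriorExtractor, FusionSegmenter

ext = EdgePriorExtractor(channel_size=64)
X = ext.transform([img])                      # (n, 5, 64, 64)
est = FusionSegmenter(combo="Io_cn2_log_pm", family="unet", depth=3,
                      base_filters=8, input_size=64, max_steps=200)
# est.fit(X, y) with y of shape (n, 64, 64); est.predict(X) -> masks
```

Both estimators follow scikit-learn conventions (`get_params`,
`set_params`, fitted attributes with trailing underscores) and compose
with sklearn pipelines and model selection.

A command-line interface covers the same workflows:

```bash
lungprior phantom --n 8 --seed 0 --family A --outdir data/
lungprior extract --input data/images --outdir channels/ --qc
lungprior sweep --data data/ --seed 0 --out sweep.csv
```

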